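"""Cumulative net fluxes between connected macrobasins and DOT rendering.

The cumulative flux from basin b to basin a over [0, tau] is

    J_ab(tau) = integral_0^tau [ K_{a<-b} P_b(t) - K_{b<-a} P_a(t) ] dt

and is evaluated analytically mode by mode: each decaying mode contributes
(e^{lambda tau} - 1)/lambda, and the stationary mode contributes nothing
because the equilibrium flux across every edge vanishes under detailed
balance (which also makes tau = infinity finite: -1/lambda per mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from foldonkinetics.free_energy import FreeEnergyTable
from foldonkinetics.network import (
    RateMatrix,
    SpectralDecomposition,
    _check_populations,
    _detailed_balance_residual,
    hamming,
)


class FluxError(ValueError):
    pass


@dataclass(frozen=True)
class FluxMatrix:
    """Antisymmetric cumulative net fluxes; entry (a, b) = net flow b -> a."""

    labels: tuple[str, ...]
    entries: np.ndarray  # (n, n)
    tau: float  # math.inf for the equilibrium limit

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise FluxError("flux matrix shape must match labels")
        if m.size:
            if np.max(np.abs(m + m.T)) > 1e-12 * max(1.0, np.max(np.abs(m))):
                raise FluxError("flux matrix must be antisymmetric")
            m = 0.5 * (m - m.T)
        object.__setattr__(self, "entries", m)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def net(self, to_label: str, from_label: str) -> float:
        return float(self.entries[self.index(to_label), self.index(from_label)])


def cumulative_flux(
    decomp: SpectralDecomposition,
    K: RateMatrix,
    p0: np.ndarray,
    tau: float = math.inf,
) -> FluxMatrix:
    """Cumulative net flux over [0, tau] from initial populations p0."""
    if decomp.labels != K.labels:
        raise FluxError("decomposition and rate matrix labels differ")
    if tau < 0:
        raise FluxError("tau must be >= 0")
    p0 = _check_populations(p0, K.n_states)

    scale = max(K.k0, np.max(np.abs(K.matrix)))
    db_ok = _detailed_balance_residual(K.matrix, decomp.equilibrium) < 1e-10 * scale
    if math.isinf(tau) and not db_ok:
        raise FluxError(
            "tau = infinity requires detailed balance (fluxes would diverge)"
        )

    c = decomp.modes_inv @ p0
    lam = decomp.eigenvalues
    tol = 1e-12 * max(scale, 1.0)
    integrals = np.zeros_like(lam)
    for n, l in enumerate(lam):
        if l > -tol:
            # stationary mode: zero net edge flux under detailed balance
            integrals[n] = 0.0
        elif math.isinf(tau):
            integrals[n] = -1.0 / l
        else:
            integrals[n] = (np.exp(l * tau) - 1.0) / l

    # time-integrated decaying part of P(t), per state
    m_int = decomp.modes @ (c * integrals)
    off = K.matrix - np.diag(np.diag(K.matrix))
    j = off * m_int[None, :] - (off * m_int[None, :]).T
    return FluxMatrix(labels=K.labels, entries=j, tau=tau)


def cut_balance(
    J: FluxMatrix,
    subset: set[str],
    p0: np.ndarray,
    peq: np.ndarray,
) -> float:
    """Conservation audit: |net flux into the subset - its population change|.

    At tau = infinity the total flux across any cut must equal the
    equilibrium-minus-initial population of the cut set.
    """
    if not subset:
        raise FluxError("subset must be nonempty")
    labels = J.labels
    unknown = subset - set(labels)
    if unknown:
        raise FluxError(f"unknown labels in subset: {sorted(unknown)}")
    idx = np.array([lab in subset for lab in labels])
    p0 = np.asarray(p0, dtype=float).ravel()
    peq = np.asarray(peq, dtype=float).ravel()
    flux_in = float(J.entries[np.ix_(idx, ~idx)].sum())
    change = float(peq[idx].sum() - p0[idx].sum())
    return abs(flux_in - change)


def export_flux_dot(
    J: FluxMatrix,
    table: FreeEnergyTable,
    min_width: float = 0.1,
    direction: str = "folding",
    max_width: float = 8.0,
) -> str:
    """Deterministic GraphViz DOT text for a flux matrix.

    Nodes show the label with its free energy (k_B T) in parentheses and
    carry position hints: y proportional to minus the free energy, x to the
    folded-bit fraction (a proxy for the global coordinate).  Edge pen
    widths scale linearly with |flux| relative to the maximum, floored at
    ``min_width``; edges point along the net flux.
    """
    if len(J.labels) == 0:
        raise FluxError("empty flux matrix")
    if set(J.labels) != set(table.entries):
        raise FluxError("flux matrix and free-energy table labels differ")
    labels = sorted(J.labels)
    n_bits = len(labels[0])
    j_max = float(np.max(np.abs(J.entries)))
    lines = [
        f"digraph {direction}_flux {{",
        '  graph [splines=line];',
        '  node [shape=box, fontsize=10];',
    ]
    for lab in labels:
        f = table.entries[lab]
        x = 4.0 * sum(c == "1" for c in lab) / n_bits
        y = -f
        lines.append(
            f'  "{lab}" [label="{lab}\\n({f:.2f})", pos="{x:.4f},{y:.4f}!"];'
        )
    for a in labels:
        for b in labels:
            if a >= b or hamming(a, b) != 1:
                continue
            jab = J.net(a, b)  # net flow b -> a
            src, dst = (b, a) if jab >= 0 else (a, b)
            mag = abs(jab)
            width = min_width if j_max == 0 else max(
                min_width, max_width * mag / j_max
            )
            lines.append(
                f'  "{src}" -> "{dst}" [penwidth={width:.4f}, '
                f'flux="{mag:.6e}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def dominant_pathway(J: FluxMatrix, source: str, sink: str) -> list[str]:
    """Widest-bottleneck path from source to sink on positive net fluxes.

    Among all paths maximizing the minimum edge flux, returns the
    lexicographically smallest label sequence.
    """
    labels = J.labels
    if source not in labels or sink not in labels:
        raise FluxError("source or sink not in flux matrix")
    if source == sink:
        return [source]
    # directed adjacency on strictly positive net flux
    adj: dict[str, list[tuple[str, float]]] = {lab: [] for lab in labels}
    for b in labels:
        for a in labels:
            if a == b:
                continue
            jab = J.net(a, b)
            if jab > 0:
                adj[b].append((a, jab))

    # max-bottleneck value via Dijkstra-style relaxation
    best = {lab: 0.0 for lab in labels}
    best[source] = math.inf
    todo = set(labels)
    while todo:
        u = max(todo, key=lambda lab: (best[lab], lab))
        todo.discard(u)
        if best[u] == 0.0:
            break
        for v, w in adj[u]:
            cand = min(best[u], w)
            if cand > best[v]:
                best[v] = cand
    bottleneck = best[sink]
    if bottleneck <= 0.0:
        raise FluxError(
            f"no positive-flux path from {source!r} to {sink!r}"
        )

    # lexicographically smallest path using only edges >= bottleneck
    strong = {
        b: sorted(a for a, w in adj[b] if w >= bottleneck - 1e-15 * bottleneck)
        for b in labels
    }

    def reaches(start: str, avoid: set[str]) -> bool:
        stack = [start]
        seen = {start}
        while stack:
            x = stack.pop()
            if x == sink:
                return True
            for y in strong[x]:
                if y not in seen and y not in avoid:
                    seen.add(y)
                    stack.append(y)
        return False

    path = [source]
    visited = {source}
    while path[-1] != sink:
        here = path[-1]
        for nxt in strong[here]:
            if nxt in visited:
                continue
            if nxt == sink or reaches(nxt, visited):
                path.append(nxt)
                visited.add(nxt)
                break
        else:
            raise FluxError(
                f"no positive-flux path from {source!r} to {sink!r}"
            )
    return path
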