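"""Locally connected master equation over sampled macrobasins.

Macrobasins are connected iff their binary labels differ in exactly one bit
(one foldon reconfiguration).  Transitions that lower the free energy all
proceed at the universal downhill rate k0; uphill transitions are penalized
by the Boltzmann factor of the free-energy difference:

    rate(a -> b) = k0                      if F_b - F_a <= 0
                 = k0 * exp(-(F_b - F_a))  otherwise   (F in k_B T)

Matrix convention: entry (row b, column a) is the rate a -> b, diagonals
are minus the column sums, so columns sum to zero and probability is
conserved.  Detailed balance holds by construction, so the spectrum is real
and non-positive; the slowest nonzero mode gives the observable relaxation
rate, and scanning tables over temperature traces out a chevron curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.linalg

from foldonkinetics.free_energy import FreeEnergyTable, stability


class NetworkError(ValueError):
    pass


class DisconnectedNetworkError(NetworkError):
    def __init__(self, components: list[list[str]]):
        self.components = components
        super().__init__(
            f"sampled macrobasin network is disconnected: {components}"
        )


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_connectivity(labels: set[str] | list[str]) -> list[tuple[str, str]]:
    """Undirected edges between sampled labels at Hamming distance 1."""
    labels = sorted(set(labels))
    if not labels:
        return []
    n = len(labels[0])
    if any(len(lab) != n for lab in labels):
        raise NetworkError("labels have mixed lengths")
    return [
        (a, b) for a, b in combinations(labels, 2) if hamming(a, b) == 1
    ]


def connected_components(labels: list[str]) -> list[list[str]]:
    edges = build_connectivity(labels)
    adj: dict[str, set[str]] = {lab: set() for lab in sorted(set(labels))}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for lab in sorted(adj):
        if lab in seen:
            continue
        comp = []
        stack = [lab]
        seen.add(lab)
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        comps.append(sorted(comp))
    return comps


@dataclass(frozen=True)
class RateMatrix:
    """Master-equation operator over an ordered set of macrobasin labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # (n, n); entry (row b, col a) = rate a -> b
    k0: float
    temperature: float
    free_energies: np.ndarray  # (n,) in k_B T, aligned with labels

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise NetworkError("matrix shape must match label count")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self,
            "free_energies",
            np.asarray(self.free_energies, dtype=float).ravel(),
        )

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def equilibrium(self) -> np.ndarray:
        """Boltzmann distribution of the stored free energies."""
        w = np.exp(-(self.free_energies - self.free_energies.min()))
        return w / w.sum()

    def validate(self, atol: float = 1e-12) -> None:
        m = self.matrix
        off = m - np.diag(np.diag(m))
        if np.any(off < -atol * self.k0):
            raise NetworkError("negative off-diagonal rate")
        col_sums = m.sum(axis=0)
        if np.max(np.abs(col_sums)) > atol * self.k0 * self.n_states:
            raise NetworkError("columns do not sum to zero")
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j and off[j, i] != 0 and hamming(a, b) != 1:
                    raise NetworkError(
                        f"rate between non-adjacent labels {a!r}, {b!r}"
                    )


def build_rate_matrix(table: FreeEnergyTable, k0: float = 1e6) -> RateMatrix:
    """Rates on the Hamming-1 network of the table's sampled labels."""
    if k0 <= 0:
        raise NetworkError("k0 must be positive")
    labels = tuple(sorted(table.entries))
    if not labels:
        raise NetworkError("empty free-energy table")
    f = np.array([table.entries[a] for a in labels])
    n = len(labels)
    m = np.zeros((n, n))
    for a, b in build_connectivity(list(labels)):
        i, j = labels.index(a), labels.index(b)
        df = f[j] - f[i]  # a -> b
        m[j, i] = k0 if df <= 0 else k0 * np.exp(-df)
        m[i, j] = k0 if -df <= 0 else k0 * np.exp(df)
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=0))
    return RateMatrix(
        labels=labels,
        matrix=m,
        k0=k0,
        temperature=table.temperature,
        free_energies=f,
    )


@dataclass
class SpectralDecomposition:
    """Eigen-solution of the rate matrix, sorted by descending eigenvalue."""

    labels: tuple[str, ...]
    eigenvalues: np.ndarray  # descending, real
    modes: np.ndarray  # columns are right eigenvectors of K
    modes_inv: np.ndarray  # V^{-1}
    k0: float
    equilibrium: np.ndarray
    coefficients: np.ndarray | None = None  # V^{-1} P0 when P0 given

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def coefficients_for(self, p0: np.ndarray) -> np.ndarray:
        p0 = _check_populations(p0, self.n_states)
        return self.modes_inv @ p0


def _check_populations(p0: np.ndarray, n: int) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float).ravel()
    if len(p0) != n:
        raise NetworkError("population vector length mismatch")
    if np.any(p0 < -1e-12):
        raise NetworkError("populations must be non-negative")
    if abs(p0.sum() - 1.0) > 1e-10:
        raise NetworkError("populations must sum to 1")
    return np.clip(p0, 0.0, None)


def _detailed_balance_residual(m: np.ndarray, pi: np.ndarray) -> float:
    flux = m * pi[None, :]  # entry (b, a) = K_ba * pi_a
    return float(np.max(np.abs(flux - flux.T)))


def spectral_solve(
    K: RateMatrix, p0: np.ndarray | None = None
) -> SpectralDecomposition:
    """Diagonalize K via the detailed-balance symmetrization.

    With pi the Boltzmann weights, S = P^{-1/2} K P^{1/2} is symmetric, so
    ``eigh`` yields a real spectrum and well-conditioned modes.  A matrix
    that violates detailed balance falls back to the general solver with a
    warning.
    """
    import warnings

    pi = K.equilibrium()
    m = K.matrix
    scale = max(K.k0, np.max(np.abs(m)))
    if _detailed_balance_residual(m, pi) < 1e-10 * scale:
        sqrt_pi = np.sqrt(pi)
        s = m * (sqrt_pi[None, :] / sqrt_pi[:, None])
        s = 0.5 * (s + s.T)
        evals, u = np.linalg.eigh(s)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        u = u[:, order]
        modes = sqrt_pi[:, None] * u
        modes_inv = u.T / sqrt_pi[None, :]
    else:
        warnings.warn(
            "rate matrix violates detailed balance; using general eigensolver",
            stacklevel=2,
        )
        evals, v = scipy.linalg.eig(m)
        order = np.argsort(evals.real)[::-1]
        evals = evals[order].real
        modes = v[:, order].real
        modes_inv = np.linalg.inv(modes)

    decomp = SpectralDecomposition(
        labels=K.labels,
        eigenvalues=evals,
        modes=modes,
        modes_inv=modes_inv,
        k0=K.k0,
        equilibrium=pi,
    )
    if p0 is not None:
        decomp.coefficients = decomp.coefficients_for(p0)
    return decomp


def propagate(
    decomp: SpectralDecomposition,
    p0: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """P_i(t) = sum_n c_n V_in exp(lambda_n t); shape (n_times, n_states)."""
    p0 = _check_populations(p0, decomp.n_states)
    c = decomp.modes_inv @ p0
    times = np.asarray(times, dtype=float).ravel()
    lam = np.minimum(decomp.eigenvalues, 0.0)  # clip zero-mode jitter
    pops = np.einsum(
        "in,n,tn->ti", decomp.modes, c, np.exp(np.outer(times, lam))
    )
    if np.min(pops) < -1e-8:
        raise NetworkError(
            f"propagation produced negative population ({np.min(pops):.2e})"
        )
    sums = pops.sum(axis=1)
    if np.max(np.abs(sums - 1.0)) > 1e-10:
        raise NetworkError("propagated populations do not sum to 1")
    return pops


@dataclass(frozen=True)
class Relaxation:
    """Observable relaxation rate plus the spectral-gap diagnostic."""

    k_obs: float
    gap_ratio: float  # lambda_1 / lambda_2; small => single-exponential

    def __float__(self) -> float:
        return self.k_obs


def relaxation_rate(decomp: SpectralDecomposition) -> Relaxation:
    """|largest eigenvalue strictly below zero| and the gap to the next."""
    if decomp.n_states < 2:
        raise NetworkError("need >= 2 states for a relaxation rate")
    tol = 1e-10 * decomp.k0
    zero_modes = int(np.sum(decomp.eigenvalues > -tol))
    if zero_modes > 1:
        raise DisconnectedNetworkError(connected_components(list(decomp.labels)))
    lam1 = decomp.eigenvalues[1]
    lam2 = decomp.eigenvalues[2] if decomp.n_states > 2 else -np.inf
    gap = float(lam1 / lam2) if np.isfinite(lam2) and lam2 != 0 else 0.0
    return Relaxation(k_obs=float(-lam1), gap_ratio=gap)


@dataclass(frozen=True)
class ChevronCurve:
    """(stability in k_B T, log10 relaxation rate) points, sorted by x."""

    points: tuple[tuple[float, float], ...]
    temperatures: tuple[float, ...]
    skipped: tuple[float, ...] = ()

    @property
    def stabilities(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def log10_rates(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def chevron_scan(
    tables: list[FreeEnergyTable], k0: float = 1e6
) -> ChevronCurve:
    """One (stability, log10 k_obs) point per table whose folded and
    unfolded endpoints were both sampled."""
    points = []
    used = []
    skipped = []
    for table in tables:
        try:
            x = stability(table)
        except Exception:
            skipped.append(table.temperature)
            continue
        K = build_rate_matrix(table, k0=k0)
        decomp = spectral_solve(K)
        rate = relaxation_rate(decomp)
        points.append((x, float(np.log10(rate.k_obs))))
        used.append(table.temperature)
    if len(points) < 2:
        raise NetworkError(
            "chevron needs >= 2 temperatures with both endpoints sampled"
        )
    order = np.argsort([p[0] for p in points])
    return ChevronCurve(
        points=tuple(points[i] for i in order),
        temperatures=tuple(used[i] for i in order),
        skipped=tuple(skipped),
    )
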