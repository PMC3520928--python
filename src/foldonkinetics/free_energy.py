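"""Macrobasin free energies from umbrella windows via multistate reweighting.

Windows are biased simulations (harmonic restraint on the global coordinate,
possibly at different temperatures).  The self-consistent multistate
estimator combines all frames into per-frame weights at any requested
unbiased target temperature; macrobasin free energies follow by summing
weights over frames sharing a label.  Energies use k_B = 1, so reduced
potentials are u_k(x) = (E(x) + kappa_k (Q(x) - Q0_k)^2) / T_k and all free
energies are reported in units of k_B T at the table's own temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


class FreeEnergyError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class WindowSamples:
    """Frames from one umbrella window.

    ``energy`` and ``global_q`` are the exact per-frame model energy and
    global coordinate (required for reweighting); ``foldon_q`` and ``labels``
    ride along for discretization.
    """

    window_id: str
    bias_center: float
    bias_strength: float
    temperature: float
    energy: np.ndarray
    global_q: np.ndarray
    foldon_q: np.ndarray | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float).ravel()
        q = np.asarray(self.global_q, dtype=float).ravel()
        if len(e) != len(q) or len(e) < 1:
            raise FreeEnergyError("energy and global_q must align, >= 1 frame")
        if self.bias_strength < 0:
            raise FreeEnergyError("bias strength must be >= 0")
        if self.temperature <= 0:
            raise FreeEnergyError("temperature must be positive")
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "global_q", q)
        if self.labels is not None and len(self.labels) != len(e):
            raise FreeEnergyError("labels must align with frames")

    @property
    def n_frames(self) -> int:
        return len(self.energy)

    def reduced_potential(
        self, energy: np.ndarray, global_q: np.ndarray
    ) -> np.ndarray:
        bias = self.bias_strength * (global_q - self.bias_center) ** 2
        return (energy + bias) / self.temperature


@dataclass(frozen=True)
class FreeEnergyTable:
    """Macrobasin label -> free energy in k_B T, with a zero-gauge label."""

    temperature: float
    entries: dict[str, float]
    gauge: str
    stderr: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.gauge not in self.entries:
            raise FreeEnergyError(f"gauge label {self.gauge!r} not in table")
        if abs(self.entries[self.gauge]) > 1e-12:
            raise FreeEnergyError("gauge entry must be exactly 0")
        if not all(np.isfinite(v) for v in self.entries.values()):
            raise FreeEnergyError("free energies must be finite")

    @property
    def labels(self) -> list[str]:
        return sorted(self.entries)

    def values(self) -> np.ndarray:
        return np.array([self.entries[a] for a in self.labels])


@dataclass
class MbarResult:
    """Solved estimator state: window free energies and per-frame mixture
    log-denominators, reusable for any unbiased target temperature."""

    windows: list[WindowSamples]
    f: np.ndarray  # per-window reduced free energies, gauge f[0] = 0
    log_denominator: np.ndarray  # per concatenated frame
    energy: np.ndarray  # concatenated
    global_q: np.ndarray  # concatenated
    n_iter: int = 0

    def weights(
        self,
        temperature: float,
        bias_strength: float = 0.0,
        bias_center: float = 0.0,
    ) -> tuple[np.ndarray, float]:
        """Normalized per-frame weights and the reduced free energy of the
        target state (relative to window 1's gauge)."""
        bias = bias_strength * (self.global_q - bias_center) ** 2
        u_target = (self.energy + bias) / temperature
        logw = -u_target - self.log_denominator
        f_target = -logsumexp(logw)
        w = np.exp(logw + f_target)
        return w / w.sum(), float(f_target)

    def concatenated_labels(self) -> list[str]:
        labels: list[str] = []
        for w in self.windows:
            if w.labels is None:
                raise FreeEnergyError(
                    f"window {w.window_id!r} carries no labels"
                )
            labels.extend(w.labels)
        return labels


def _reduced_potential_matrix(windows: list[WindowSamples]) -> np.ndarray:
    energy = np.concatenate([w.energy for w in windows])
    global_q = np.concatenate([w.global_q for w in windows])
    return (
        np.stack([w.reduced_potential(energy, global_q) for w in windows]),
        energy,
        global_q,
    )


def mbar_solve(
    windows: list[WindowSamples],
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> MbarResult:
    """Solve the self-consistent multistate equations.

    A convex quasi-Newton minimization supplies the starting point; plain
    self-consistent iteration then polishes until the max absolute change of
    any window free energy per sweep is below ``tol``.
    """
    if not windows:
        raise FreeEnergyError("need at least one window")
    u_kn, energy, global_q = _reduced_potential_matrix(windows)
    n_k = np.array([w.n_frames for w in windows], dtype=float)
    log_nk = np.log(n_k)
    n_win = len(windows)

    def objective(f: np.ndarray) -> tuple[float, np.ndarray]:
        log_d = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
        val = log_d.sum() - float(n_k @ f)
        w = np.exp(log_nk[:, None] + f[:, None] - u_kn - log_d[None, :])
        grad = w.sum(axis=1) - n_k
        return val, grad

    f = np.zeros(n_win)
    if n_win > 1:
        res = minimize(objective, f, jac=True, method="L-BFGS-B",
                       options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
        f = res.x - res.x[0]

    n_iter = 0
    while True:
        log_d = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - log_d[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        n_iter += 1
        if delta < tol:
            break
        if n_iter >= max_iter:
            raise ConvergenceError(
                f"estimator not converged after {max_iter} iterations "
                f"(residual {delta:.3e})"
            )

    log_d = logsumexp(log_nk[:, None] + f[:, None] - u_kn, axis=0)
    _warn_if_disconnected(windows, u_kn, f, log_nk, log_d)
    return MbarResult(
        windows=list(windows),
        f=f,
        log_denominator=log_d,
        energy=energy,
        global_q=global_q,
        n_iter=n_iter,
    )


def _warn_if_disconnected(
    windows: list[WindowSamples],
    u_kn: np.ndarray,
    f: np.ndarray,
    log_nk: np.ndarray,
    log_d: np.ndarray,
) -> None:
    """Warn when some windows share essentially no configuration-space
    support with the rest (estimates remain defined but high-variance)."""
    n_win = len(windows)
    if n_win < 2:
        return
    logw = f[:, None] - u_kn - log_d[None, :]  # rows sum to ~0 in log space
    w = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    overlap = w @ w.T  # (K, K), symmetric, positive when support is shared
    seen = {0}
    frontier = [0]
    while frontier:
        k = frontier.pop()
        for l in range(n_win):
            if l not in seen and overlap[k, l] > 1e-10:
                seen.add(l)
                frontier.append(l)
    if len(seen) < n_win:
        missing = [windows[k].window_id for k in range(n_win) if k not in seen]
        warnings.warn(
            "umbrella windows with negligible overlap detected "
            f"({missing}); free energy estimates may have large variance",
            stacklevel=3,
        )


def macrobasin_free_energies(
    weights: np.ndarray,
    labels: list[str],
    temperature: float,
    gauge: str | None = None,
    stderr: dict[str, float] | None = None,
) -> FreeEnergyTable:
    """F_a = -ln(sum of weights of frames labelled a), gauge-shifted.

    Gauge defaults to the all-zeros label when sampled, else the lowest-F
    label.  Only labels carrying weight appear.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    if len(weights) != len(labels):
        raise FreeEnergyError("weights and labels must align")
    totals: dict[str, float] = {}
    for w, lab in zip(weights, labels):
        totals[lab] = totals.get(lab, 0.0) + w
    totals = {lab: t for lab, t in totals.items() if t > 0}
    if not totals:
        raise FreeEnergyError("no label carries weight")
    raw = {lab: -np.log(t) for lab, t in totals.items()}
    if gauge is None:
        zeros = "0" * len(next(iter(raw)))
        gauge = zeros if zeros in raw else min(raw, key=lambda a: raw[a])
    if gauge not in raw:
        raise FreeEnergyError(f"gauge label {gauge!r} has zero weight")
    shift = raw[gauge]
    entries = {lab: v - shift for lab, v in raw.items()}
    entries[gauge] = 0.0
    return FreeEnergyTable(
        temperature=temperature, entries=entries, gauge=gauge, stderr=stderr
    )


def stability(table: FreeEnergyTable) -> float:
    """F(all folded) - F(all unfolded), in k_B T."""
    n = len(next(iter(table.entries)))
    folded, unfolded = "1" * n, "0" * n
    for lab in (folded, unfolded):
        if lab not in table.entries:
            raise FreeEnergyError(
                f"macrobasin {lab!r} unsampled: stability undefined"
            )
    return table.entries[folded] - table.entries[unfolded]


def bootstrap_free_energy_stderr(
    windows: list[WindowSamples],
    temperature: float,
    gauge: str | None = None,
    n_boot: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
) -> dict[str, float]:
    """Bootstrap stderr of macrobasin free energies (resampling frames
    within windows)."""
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {}
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            idx = rng.integers(0, w.n_frames, size=w.n_frames)
            resampled.append(
                WindowSamples(
                    window_id=w.window_id,
                    bias_center=w.bias_center,
                    bias_strength=w.bias_strength,
                    temperature=w.temperature,
                    energy=w.energy[idx],
                    global_q=w.global_q[idx],
                    labels=tuple(np.asarray(w.labels)[idx])
                    if w.labels is not None
                    else None,
                )
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = mbar_solve(resampled, tol=tol)
        weights, _ = result.weights(temperature)
        table = macrobasin_free_energies(
            weights, result.concatenated_labels(), temperature, gauge=gauge
        )
        for lab, val in table.entries.items():
            samples.setdefault(lab, []).append(val)
    return {
        lab: float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        for lab, vals in samples.items()
    }
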