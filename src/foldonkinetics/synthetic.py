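"""Ground-truth foldon landscapes with exactly enumerable free energies.

A landscape assigns every binary foldon configuration sigma an energy

    E(sigma) = - sum_i eps_i sigma_i - sum_i J_i sigma_i sigma_{i+1}

plus an integer degeneracy per *unfolded* foldon (entropy of the unfolded
state), so the reduced free energy at temperature T (k_B = 1) is

    F(sigma)/T = E(sigma)/T - sum_i (1 - sigma_i) ln m_i      (+ const).

Because the degeneracy is temperature independent it acts as a state
multiplicity: Metropolis sampling over configurations with the degeneracy
folded into the acceptance ratio draws from exp(-E/T) on the degenerate
configuration measure, which is exactly what the multistate reweighting
stage assumes.  That makes every downstream estimate checkable against the
2^N enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from foldonkinetics.free_energy import FreeEnergyTable, WindowSamples
from foldonkinetics.free_energy import macrobasin_free_energies, mbar_solve


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticLandscape:
    """Ising-like foldon landscape with per-foldon unfolded degeneracy."""

    foldon_energy: np.ndarray  # eps_i, stabilization when folded
    coupling: np.ndarray  # J_i between adjacent folded foldons, len N-1
    degeneracy: np.ndarray  # integer microstate count of the unfolded foldon
    seed: int = 0

    def __post_init__(self) -> None:
        eps = np.asarray(self.foldon_energy, dtype=float).ravel()
        n = len(eps)
        if n < 1 or n > 14:
            raise SyntheticError("n_foldons must be in 1..14 (2^N enumeration)")
        coup = np.asarray(self.coupling, dtype=float).ravel()
        if len(coup) != max(n - 1, 0):
            raise SyntheticError("coupling must have length n_foldons - 1")
        deg = np.asarray(self.degeneracy, dtype=int).ravel()
        if len(deg) != n or np.any(deg < 1):
            raise SyntheticError("degeneracy must be >= 1 per foldon")
        object.__setattr__(self, "foldon_energy", eps)
        object.__setattr__(self, "coupling", coup)
        object.__setattr__(self, "degeneracy", deg)

    @property
    def n_foldons(self) -> int:
        return len(self.foldon_energy)

    @property
    def foldon_entropy(self) -> np.ndarray:
        """Entropy loss on folding each foldon, ln(degeneracy)."""
        return np.log(self.degeneracy.astype(float))

    def states(self) -> list[tuple[int, ...]]:
        return list(product((0, 1), repeat=self.n_foldons))

    def energy(self, sigma) -> float:
        s = np.asarray(sigma, dtype=float)
        e = -float(self.foldon_energy @ s)
        if self.n_foldons > 1:
            e -= float(self.coupling @ (s[:-1] * s[1:]))
        return e

    def log_degeneracy(self, sigma) -> float:
        s = np.asarray(sigma, dtype=float)
        return float((1.0 - s) @ self.foldon_entropy)

    @staticmethod
    def label(sigma) -> str:
        return "".join(str(int(x)) for x in sigma)

    @staticmethod
    def global_q(sigma) -> float:
        s = np.asarray(sigma, dtype=float)
        return float(s.mean())


def default_landscape(n_foldons: int = 4, seed: int = 0) -> SyntheticLandscape:
    """Moderately cooperative reference landscape used by tests and the CLI."""
    return SyntheticLandscape(
        foldon_energy=np.full(n_foldons, 1.0),
        coupling=np.full(max(n_foldons - 1, 0), 0.3),
        degeneracy=np.full(n_foldons, 3, dtype=int),
        seed=seed,
    )


def cooperative_landscape(
    n_foldons: int = 4, seed: int = 0, foldon_energy: float = 3.0,
    degeneracy: int = 148,
) -> SyntheticLandscape:
    """Strongly cooperative landscape with uphill intermediates.

    The adjacent coupling is fixed so the fully folded and fully unfolded
    states are exactly degenerate at T = 1 (k_B = 1); partially folded
    states then sit several k_BT uphill, producing a V-shaped relaxation
    chevron with a barrier near the folding temperature.
    """
    s = math.log(degeneracy)
    coupling = n_foldons * (s - foldon_energy) / max(n_foldons - 1, 1)
    if coupling <= 0:
        raise SyntheticError("degeneracy too small for a folding barrier")
    return SyntheticLandscape(
        foldon_energy=np.full(n_foldons, foldon_energy),
        coupling=np.full(max(n_foldons - 1, 0), coupling),
        degeneracy=np.full(n_foldons, degeneracy, dtype=int),
        seed=seed,
    )


def exact_free_energies(
    landscape: SyntheticLandscape, temperature: float
) -> FreeEnergyTable:
    """Brute-force 2^N enumeration; F in k_B T, gauge all-zeros = 0."""
    if temperature <= 0:
        raise SyntheticError("temperature must be positive")
    entries = {}
    zeros = "0" * landscape.n_foldons
    ref = landscape.log_degeneracy([0] * landscape.n_foldons)
    for sigma in landscape.states():
        beta_f = landscape.energy(sigma) / temperature - (
            landscape.log_degeneracy(sigma) - ref
        )
        entries[landscape.label(sigma)] = beta_f
    shift = entries[zeros]
    entries = {lab: v - shift for lab, v in entries.items()}
    entries[zeros] = 0.0
    return FreeEnergyTable(
        temperature=temperature, entries=entries, gauge=zeros
    )


def equilibrium_probabilities(
    landscape: SyntheticLandscape, temperature: float
) -> dict[str, float]:
    table = exact_free_energies(landscape, temperature)
    f = np.array([table.entries[lab] for lab in table.labels])
    w = np.exp(-(f - f.min()))
    w /= w.sum()
    return dict(zip(table.labels, w))


def _emit_foldon_qs(
    sigma: tuple[int, ...],
    threshold: float,
    mislabel_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous q per foldon, concentrated on the correct side of the
    threshold; with probability ``mislabel_rate`` a foldon lands on the
    wrong side, exercising threshold robustness downstream."""
    qs = np.empty(len(sigma))
    for i, s in enumerate(sigma):
        folded = bool(s)
        if rng.random() < mislabel_rate:
            folded = not folded
        b = rng.beta(2.0, 2.0)
        qs[i] = threshold + (1.0 - threshold) * b if folded else threshold * b
    return qs


def sample_umbrella_windows(
    landscape: SyntheticLandscape,
    windows: list[tuple[float, float, float, int]],
    threshold: float = 0.6,
    mislabel_rate: float = 0.001,
    seed: int | None = None,
    sweeps_per_frame: int = 1,
    return_true_states: bool = False,
):
    """Metropolis sampling of each (kappa, center, temperature, n_frames)
    umbrella window over the 2^N configurations.

    Moves are single-foldon flips (mirroring the kinetic model's Hamming-1
    connectivity); the unfolded-state degeneracy enters the acceptance
    ratio.  The first 10% of frames are burned in.  Frames record the exact
    model energy and global coordinate plus emitted continuous per-foldon q
    values and their threshold labels.
    """
    if seed is None:
        seed = landscape.seed
    rng = np.random.default_rng(seed)
    n = landscape.n_foldons
    log_m = landscape.foldon_entropy
    out = []
    true_states_all = []
    for w_idx, (kappa, center, temperature, n_frames) in enumerate(windows):
        if n_frames < 100:
            raise SyntheticError("need >= 100 frames per window")
        beta = 1.0 / temperature

        def total_energy(sig: np.ndarray) -> float:
            q = sig.mean()
            return landscape.energy(sig) + kappa * (q - center) ** 2

        # start at the biased free-energy minimum (enumerable) so no
        # equilibration cliff precedes burn-in
        biased_f = [
            beta * total_energy(np.array(s)) - landscape.log_degeneracy(s)
            for s in landscape.states()
        ]
        order = np.argsort(biased_f)
        sigma = np.array(landscape.states()[int(order[0])], dtype=int)
        # if a competing state sits within 2 kT, accepted moves are expected
        moves_expected = (
            len(order) > 1 and biased_f[int(order[1])] - biased_f[int(order[0])] < 2.0
        )
        e_tot = total_energy(sigma)
        burn = n_frames // 10
        energies = np.empty(n_frames)
        qs_global = np.empty(n_frames)
        foldon_qs = np.empty((n_frames, n))
        labels = []
        true_states = []
        accepted = 0
        for frame in range(burn + n_frames):
            for _ in range(sweeps_per_frame * n):
                i = int(rng.integers(n))
                sigma[i] ^= 1
                e_new = total_energy(sigma)
                # flipping to unfolded gains the degeneracy factor m_i
                log_ratio = -beta * (e_new - e_tot) + (
                    log_m[i] if sigma[i] == 0 else -log_m[i]
                )
                if np.log(rng.random()) < log_ratio:
                    e_tot = e_new
                    accepted += 1
                else:
                    sigma[i] ^= 1
            if frame < burn:
                continue
            k = frame - burn
            energies[k] = landscape.energy(sigma)
            qs_global[k] = sigma.mean()
            foldon_qs[k] = _emit_foldon_qs(
                tuple(sigma), threshold, mislabel_rate, rng
            )
            labels.append("".join("1" if q > threshold else "0"
                                  for q in foldon_qs[k]))
            true_states.append(landscape.label(sigma))
        if accepted == 0 and moves_expected:
            raise SyntheticError(
                f"window {w_idx} accepted no moves despite competing states "
                "within 2 kT of the biased minimum"
            )
        out.append(
            WindowSamples(
                window_id=f"w{w_idx}",
                bias_center=float(center),
                bias_strength=float(kappa),
                temperature=float(temperature),
                energy=energies,
                global_q=qs_global,
                foldon_q=foldon_qs,
                labels=tuple(labels),
            )
        )
        true_states_all.append(true_states)
    if return_true_states:
        return out, true_states_all
    return out


def default_protocol(
    n_windows: int = 5, n_frames: int = 5000, temperature: float = 1.0,
    kappa: float = 10.0,
) -> list[tuple[float, float, float, int]]:
    """Evenly spaced umbrella centers on [0, 1] at one temperature."""
    centers = np.linspace(0.0, 1.0, n_windows)
    return [(kappa, float(c), temperature, n_frames) for c in centers]


def roundtrip_recovery(
    landscape: SyntheticLandscape,
    protocol: list[tuple[float, float, float, int]],
    seed: int = 0,
    target_temperature: float | None = None,
    threshold: float = 0.6,
    mislabel_rate: float = 0.001,
    min_probability: float = 1e-4,
) -> dict:
    """Sample -> label -> reweight -> macrobasin F, compared to enumeration.

    Reports the max absolute error over macrobasins whose exact equilibrium
    probability exceeds ``min_probability``.
    """
    if target_temperature is None:
        target_temperature = protocol[0][2]
    windows = sample_umbrella_windows(
        landscape, protocol, threshold=threshold,
        mislabel_rate=mislabel_rate, seed=seed,
    )
    result = mbar_solve(windows)
    weights, _ = result.weights(target_temperature)
    zeros = "0" * landscape.n_foldons
    est = macrobasin_free_energies(
        weights, result.concatenated_labels(), target_temperature, gauge=zeros
    )
    exact = exact_free_energies(landscape, target_temperature)
    probs = equilibrium_probabilities(landscape, target_temperature)
    errors = {}
    for lab, p in probs.items():
        if p <= min_probability:
            continue
        if lab not in est.entries:
            errors[lab] = float("inf")
        else:
            errors[lab] = abs(est.entries[lab] - exact.entries[lab])
    return {
        "max_abs_error": max(errors.values()) if errors else float("nan"),
        "errors": errors,
        "n_frames_total": sum(w.n_frames for w in windows),
        "estimated": est,
        "exact": exact,
    }
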