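import numpy as np
import pytest

from foldonkinetics.free_energy import FreeEnergyTable
from foldonkinetics.synthetic import default_landscape


def make_pdb(coords, chain="A", atom_names=None):
    """Minimal fixed-column PDB text; one residue per coordinate."""
    lines = []
    serial = 1
    for k, xyz in enumerate(coords):
        names = atom_names[k] if atom_names else ["N", "CA", "C"]
        for name in names:
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA {chain}{k + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def collinear_coords(n, spacing=3.8):
    return [(spacing * k, 0.0, 0.0) for k in range(n)]


def random_table(rng, n_foldons, spread=2.0, temperature=1.0):
    """Free-energy table over all 2^N labels with random entries."""
    labels = [
        format(k, f"0{n_foldons}b") for k in range(2**n_foldons)
    ]
    f = rng.normal(0.0, spread, size=len(labels))
    zeros = "0" * n_foldons
    entries = dict(zip(labels, f - f[0]))
    entries[zeros] = 0.0
    return FreeEnergyTable(
        temperature=temperature, entries=entries, gauge=zeros
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def landscape4():
    return default_landscape(4)
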