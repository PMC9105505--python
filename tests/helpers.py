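"""Shared builders for test fixtures and oracles."""

import numpy as np

from shp2md.structure_io import Atom, Structure


def make_atom(
    serial: int,
    name: str = "CA",
    element: str = "C",
    res: int = 1,
    chain: str = "A",
    pos=(0.0, 0.0, 0.0),
    radius: float = 1.70,
    res_name: str = "ALA",
) -> Atom:
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=res_name,
        residue_number=res,
        chain=chain,
        position=np.asarray(pos, dtype=float),
        vdw_radius=radius,
    )


def random_structure(n_atoms: int, seed: int, box: float = 20.0) -> Structure:
    """Random heavy-atom cloud, one atom per residue, for oracle tests."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n_atoms, 3))
    atoms = [
        make_atom(i + 1, name="CA", res=i + 1, pos=pos[i]) for i in range(n_atoms)
    ]
    return Structure(atoms, label=f"random-{seed}")


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
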