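"""CoMFA-style molecular interaction fields on a shared lattice.

Steric (Lennard-Jones 6-12) and electrostatic (Coulomb, distance-dependent
dielectric eps(r) = r) probe energies are evaluated on a regular grid that
extends at least a fixed margin (default 4.0 A) beyond the van der Waals
envelope of every aligned molecule, at 2.0 A spacing.  Energies above
+30 kcal/mol are truncated to 30.0 (the electrostatic term is clipped
symmetrically at -30.0), and descriptor columns whose energy variance falls
below a sigma threshold (default 2.0 kcal/mol) are discarded.

Lennard-Jones parameters are a standard Tripos-like table (radius in A,
well depth in kcal/mol); exact commercial force-field energies are not
targeted, so downstream checks are property-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from naphqsar.structures import Conformer

COULOMB_KCAL = 332.06  # kcal*A/(mol*e^2)
ENERGY_CAP = 30.0  # kcal/mol

# element -> (vdW radius A, epsilon kcal/mol); Tripos-like values
LJ_PARAMS = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "S": (1.80, 0.314),
}


class Probe(NamedTuple):
    element: str
    charge: float


#: the three probes used for field generation: sp3 carbon at +1 and 0, H at +1
PROBES = {
    "C+1": Probe("C", 1.0),
    "C0": Probe("C", 0.0),
    "H+1": Probe("H", 1.0),
}


@dataclass(frozen=True)
class FieldLattice:
    """Regular axis-aligned grid: origin, spacing, per-axis point counts."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]
    probe: Probe = PROBES["C+1"]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), x fastest."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.counts[k]) for k in range(3)
        ]
        zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def _lj_radius(symbol: str) -> float:
    return LJ_PARAMS.get(symbol, LJ_PARAMS["C"])[0]


def make_lattice(
    conformers: Iterable[Conformer],
    spacing: float = 2.0,
    margin: float = 4.0,
    probe: Probe | str = "C+1",
) -> FieldLattice:
    """Smallest grid at ``spacing`` covering every vdW envelope plus margin."""
    conformers = list(conformers)
    if not conformers:
        raise ValueError("no conformers given")
    if isinstance(probe, str):
        probe = PROBES[probe]
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for conf in conformers:
        radii = np.array([_lj_radius(s) for s in conf.symbols])
        xyz = conf.coords
        lo = np.minimum(lo, (xyz - radii[:, None]).min(axis=0))
        hi = np.maximum(hi, (xyz + radii[:, None]).max(axis=0))
    lo -= margin
    hi += margin
    counts = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return FieldLattice(origin=tuple(lo), spacing=spacing, counts=counts, probe=probe)


def compute_fields(
    conformer: Conformer, lattice: FieldLattice, probe: Probe | str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Steric and electrostatic probe energies [kcal/mol] at every grid point.

    steric(p)  = sum_atoms eps_ij ((R_ij/r)^12 - 2 (R_ij/r)^6), capped at +30
    electro(p) = sum_atoms 332.06 q_probe q_atom / r^2, clipped to [-30, 30]
    (the 1/r^2 distance law folds in the distance-dependent dielectric).
    """
    if probe is None:
        probe = lattice.probe
    elif isinstance(probe, str):
        probe = PROBES[probe]
    if probe.element not in LJ_PARAMS:
        raise ValueError(f"no LJ parameters for probe element {probe.element!r}")
    pts = lattice.points()
    xyz = conformer.coords
    r = np.linalg.norm(pts[:, None, :] - xyz[None, :, :], axis=2)
    r = np.maximum(r, 1e-12)

    rp, ep = LJ_PARAMS[probe.element]
    radii = np.array([_lj_radius(s) for s in conformer.symbols])
    eps = np.array([np.sqrt(LJ_PARAMS.get(s, LJ_PARAMS["C"])[1] * ep) for s in conformer.symbols])
    rij = radii + rp
    # clamp the ratio so r -> 0 saturates numerically before the energy cap
    ratio6 = np.minimum((rij[None, :] / r) ** 6, 1e12)
    steric = np.minimum((eps[None, :] * (ratio6**2 - 2.0 * ratio6)).sum(axis=1), ENERGY_CAP)

    q = conformer.charges
    electro = COULOMB_KCAL * probe.charge * (q[None, :] / r**2).sum(axis=1)
    electro = np.clip(electro, -ENERGY_CAP, ENERGY_CAP)
    return steric, electro


def build_field_matrix(
    conformers: dict[str, Conformer],
    lattice: FieldLattice | None = None,
    probe: Probe | str = "C+1",
    spacing: float = 2.0,
    margin: float = 4.0,
) -> pd.DataFrame:
    """Compounds x descriptors field matrix.

    Columns carry a (field kind, lattice point index) MultiIndex so surviving
    columns stay traceable to grid positions after filtering.
    """
    if lattice is None:
        lattice = make_lattice(conformers.values(), spacing=spacing, margin=margin, probe=probe)
    rows = {}
    for cid, conf in conformers.items():
        steric, electro = compute_fields(conf, lattice, probe)
        rows[cid] = np.concatenate([steric, electro])
    n = lattice.n_points
    columns = pd.MultiIndex.from_tuples(
        [("steric", i) for i in range(n)] + [("electrostatic", i) for i in range(n)],
        names=["field", "point"],
    )
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def variance_filter(matrix: pd.DataFrame, sigma: float = 2.0) -> pd.DataFrame:
    """Drop descriptor columns with (sample) variance below ``sigma``."""
    if len(matrix) < 2:
        raise ValueError("variance filter needs at least 2 rows")
    keep = matrix.var(axis=0, ddof=1) >= sigma
    if not keep.any():
        raise ValueError(f"variance filter at sigma={sigma} removed every column")
    return matrix.loc[:, keep]
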