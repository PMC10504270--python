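"""Model validation: map agreement, clashes, coexpression, heptad registers.

Four independent lines of evidence for an assembled model are computed
here: (i) the masked model-to-map Pearson correlation (CCmask: correlation
restricted to voxels near model atoms); (ii) the fraction of the
thresholded density explained by the model; (iii) a simple inter-subunit
CA clash count; (iv) coexpression support from tissue nTPM profiles
(Pearson R with a two-tailed P from the F test on a simple linear
regression); plus the coiled-coil heptad-register analysis used to
interpret missense mutations at core (a/d) positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .core_io import AtomicModel, DensityMap, MapLinkError
from .density_fit import simulate_on_grid, cross_correlation


# ---------------------------------------------------------------------------
# Map-model agreement
# ---------------------------------------------------------------------------


def _voxel_mask_near_atoms(dmap: DensityMap, positions: np.ndarray,
                           radius: float) -> np.ndarray:
    """Boolean grid of voxels whose center is within ``radius`` of an atom."""
    tree = cKDTree(positions)
    shape = dmap.shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centers = dmap.index_to_world(
        np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    )
    d, _ = tree.query(centers, k=1, distance_upper_bound=radius + 1e-9)
    return (d <= radius).reshape(shape)


def cc_mask(model: AtomicModel, dmap: DensityMap, mask_radius: float = 3.0,
            resolution: float = None) -> float:
    """Masked model-to-map correlation (CCmask).

    Pearson correlation between the map and the model-simulated density,
    over voxels within ``mask_radius`` Å of any model atom.
    """
    if len(model) == 0:
        raise MapLinkError("cc_mask needs a non-empty model")
    mask = _voxel_mask_near_atoms(dmap, model.positions, mask_radius)
    if not mask.any():
        raise MapLinkError("empty mask: model does not overlap the grid")
    sim = simulate_on_grid(model, dmap, resolution)
    return cross_correlation(dmap, sim, mask=mask)


def density_explained(dmap: DensityMap, model: AtomicModel, threshold: float,
                      mask_radius: float = 3.0) -> float:
    """Fraction of above-threshold voxels within ``mask_radius`` of an atom."""
    above = dmap.values >= threshold
    n_above = int(above.sum())
    if n_above == 0:
        raise MapLinkError(f"no voxels at or above threshold {threshold}")
    if len(model) == 0:
        return 0.0
    near = _voxel_mask_near_atoms(dmap, model.positions, mask_radius)
    return float((above & near).sum() / n_above)


def clash_count(model: AtomicModel, cutoff: float = 4.0) -> int:
    """Number of CA pairs from *different* subunits closer than ``cutoff``."""
    camask = model.ca_mask()
    pos = model.positions[camask]
    sub = model.subunit_of_atoms()[camask]
    if len(pos) == 0:
        return 0
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    # query_pairs uses strict < cutoff, matching the definition
    return int(np.sum(sub[pairs[:, 0]] != sub[pairs[:, 1]]))


@dataclass
class ValidationReport:
    cc_mask: float
    density_explained: float
    clash_count: int
    xl_summary: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "cc_mask": self.cc_mask,
            "density_explained": self.density_explained,
            "clash_count": self.clash_count,
            "xl_summary": self.xl_summary,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)


def validate_model(model: AtomicModel, dmap: DensityMap, threshold: float,
                   xl_report=None, mask_radius: float = 3.0,
                   clash_cutoff: float = 4.0, resolution: float = None) -> ValidationReport:
    """Convenience wrapper producing the full validation report."""
    return ValidationReport(
        cc_mask(model, dmap, mask_radius, resolution),
        density_explained(dmap, model, threshold, mask_radius),
        clash_count(model, clash_cutoff),
        xl_report.summary() if xl_report is not None else {},
    )


# ---------------------------------------------------------------------------
# Coexpression evidence
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionTable:
    """Gene-by-tissue matrix of nTPM expression values."""

    ntpm: pd.DataFrame   # rows = genes, columns = tissues

    def __post_init__(self):
        if self.ntpm.isna().any().any():
            raise MapLinkError("nTPM table has missing cells")
        if (self.ntpm.values < 0).any():
            raise MapLinkError("nTPM values must be non-negative")

    @classmethod
    def read_csv(cls, path) -> "CoexpressionTable":
        return cls(pd.read_csv(path, index_col=0))

    def genes(self):
        return list(self.ntpm.index)

    def vector(self, gene: str) -> np.ndarray:
        if gene not in self.ntpm.index:
            raise MapLinkError(f"gene {gene!r} not in table")
        return self.ntpm.loc[gene].to_numpy(dtype=float)

    def correlate(self, gene_a: str, gene_b: str):
        return pearson_ftest(self.vector(gene_a), self.vector(gene_b))


def pearson_ftest(x, y):
    """Pearson R with a two-tailed P from the regression F test.

    ``P`` comes from ``F = r^2 (n-2) / (1 - r^2)`` on (1, n-2) degrees of
    freedom — the F test of a simple linear regression, identical to the
    two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MapLinkError("x and y must be equal-length 1D vectors")
    n = len(x)
    if n < 3:
        raise MapLinkError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise MapLinkError("correlation undefined: zero variance")
    r = float(np.dot(xc, yc) / (sx * sy))
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return r, 0.0
    f = r2 * (n - 2) / (1.0 - r2)
    p = float(stats.f.sf(f, 1, n - 2))
    return r, p


# ---------------------------------------------------------------------------
# Coiled-coil heptad registers
# ---------------------------------------------------------------------------

#: Core-forming hydrophobic residues (one-letter); G, C, P excluded.
HYDROPHOBIC = set("AVLIMFWY")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_POSITIVE = set("KR")
_NEGATIVE = set("DE")
_REGISTERS = "abcdefg"


@dataclass
class HeptadAssignment:
    """Per-residue heptad registers of a coiled-coil segment.

    ``phase_scores[p]`` is the hydrophobic fraction at a/d positions when
    the first residue carries register ``_REGISTERS[p]``; the assignment
    uses the maximizing phase (ties go to the lowest phase index, with all
    maximal phases listed in ``tied_phases``). ``polar_inclusions`` are
    the residue numbers at core (a/d) positions that fall outside the
    hydrophobic set.
    """

    sequence: str
    start_number: int
    registers: str
    phase: int
    phase_scores: np.ndarray
    tied_phases: list
    polar_inclusions: list
    proline_at_core: list

    def register_of(self, residue_number: int) -> str:
        i = residue_number - self.start_number
        if not (0 <= i < len(self.sequence)):
            raise MapLinkError(f"residue {residue_number} outside the segment")
        return self.registers[i]

    def to_frame(self) -> pd.DataFrame:
        nums = range(self.start_number, self.start_number + len(self.sequence))
        return pd.DataFrame({
            "residue_number": list(nums),
            "amino_acid": list(self.sequence),
            "register": list(self.registers),
            "core": [c in "ad" for c in self.registers],
        })


def _phase_score(sequence: str, phase: int) -> float:
    core = [
        aa for i, aa in enumerate(sequence)
        if _REGISTERS[(i + phase) % 7] in "ad"
    ]
    if not core:
        return 0.0
    return sum(aa in HYDROPHOBIC for aa in core) / len(core)


def assign_heptad_register(sequence: str, start_number: int = 1) -> HeptadAssignment:
    """Assign abcdefg heptad registers to a coiled-coil segment.

    All 7 phases are scored by the hydrophobic fraction at their a/d
    positions and the maximizing phase is chosen. Polar residues landing
    at a/d are reported as polar inclusions; prolines at a/d additionally
    raise a register-breaking warning entry (not an error).
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 7:
        raise MapLinkError("need at least one full heptad (7 residues)")
    bad = sorted(set(sequence) - _STANDARD_AA)
    if bad:
        raise MapLinkError(f"non-standard amino acids: {''.join(bad)}")
    scores = np.array([_phase_score(sequence, p) for p in range(7)])
    best = float(scores.max())
    tied = [p for p in range(7) if scores[p] == best]
    phase = tied[0]
    registers = "".join(_REGISTERS[(i + phase) % 7] for i in range(len(sequence)))
    polar, proline = [], []
    for i, (aa, reg) in enumerate(zip(sequence, registers)):
        if reg in "ad" and aa not in HYDROPHOBIC:
            polar.append(start_number + i)
            if aa == "P":
                proline.append(start_number + i)
    return HeptadAssignment(sequence, start_number, registers, phase, scores,
                            tied, polar, proline)


def map_missense_to_register(assignment: HeptadAssignment, mutations) -> pd.DataFrame:
    """Annotate missense mutations with their heptad register.

    ``mutations`` is a list of ``(residue_number, from_aa, to_aa)``. Each
    row reports the register, whether the site is a core (a/d) position,
    and whether the substitution changes the charge class.
    """

    def charge(aa: str) -> str:
        if aa in _POSITIVE:
            return "positive"
        if aa in _NEGATIVE:
            return "negative"
        return "neutral"

    rows = []
    for res_num, from_aa, to_aa in mutations:
        i = res_num - assignment.start_number
        if not (0 <= i < len(assignment.sequence)):
            raise MapLinkError(f"mutation residue {res_num} outside the segment")
        if assignment.sequence[i] != from_aa.upper():
            raise MapLinkError(
                f"residue {res_num} is {assignment.sequence[i]}, not {from_aa}"
            )
        reg = assignment.registers[i]
        rows.append({
            "residue_number": res_num,
            "from": from_aa.upper(),
            "to": to_aa.upper(),
            "register": reg,
            "core": reg in "ad",
            "charge_from": charge(from_aa.upper()),
            "charge_to": charge(to_aa.upper()),
            "charge_change": charge(from_aa.upper()) != charge(to_aa.upper()),
        })
    return pd.DataFrame(rows)
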