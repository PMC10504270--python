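"""Cross-link restraint tables and their validation against models.

Chemical cross-linkers covalently join residue pairs that must therefore
be close in the assembled structure; for the MS-cleavable DSSO linker the
expected upper bound is 35 Å between the two Cα atoms. This module parses
cross-link tables, maps them onto a model (resolving multi-copy/paralog
ambiguity by reporting every copy-pair distance and judging satisfaction
on the minimum), and summarizes the distance distributions for the
intramolecular and intermolecular link classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AtomicModel, MapLinkError

logger = logging.getLogger(__name__)

#: Expected maximum Cα–Cα distance per linker chemistry, in Å.
LINKER_MAX_DIST = {"DSSO": 35.0}


@dataclass(frozen=True)
class CrossLink:
    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    linker: str = "DSSO"
    max_dist: float = 35.0

    def __post_init__(self):
        if self.max_dist <= 0:
            raise MapLinkError("max_dist must be positive")
        if self.residue_a < 1 or self.residue_b < 1:
            raise MapLinkError("residue numbers must be >= 1")

    @property
    def kind(self) -> str:
        return "intramolecular" if self.protein_a == self.protein_b else "intermolecular"

    def key(self):
        """Unordered endpoint pair, for duplicate detection."""
        a = (self.protein_a, self.residue_a)
        b = (self.protein_b, self.residue_b)
        return (a, b) if a <= b else (b, a)


@dataclass
class CrossLinkSet:
    links: list
    source: str = ""
    #: optional per-link provenance (e.g. "true"/"decoy" for simulated sets),
    #: keyed by CrossLink.key()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for link in self.links:
            k = link.key()
            if k in seen:
                raise MapLinkError(f"duplicate cross-link {k}")
            seen.add(k)

    def __len__(self):
        return len(self.links)

    def __iter__(self):
        return iter(self.links)


def parse_xl_table(path) -> CrossLinkSet:
    """Parse a CSV cross-link table.

    Required columns: ``protein_a, residue_a, protein_b, residue_b``; an
    optional ``linker`` column defaults to DSSO (max Cα–Cα distance 35 Å)
    and an optional ``max_dist`` column overrides the linker default.
    """
    df = pd.read_csv(path)
    required = ["protein_a", "residue_a", "protein_b", "residue_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MapLinkError(f"{path}: missing columns {missing}")
    links = []
    for row_i, row in df.iterrows():
        try:
            ra, rb = int(row["residue_a"]), int(row["residue_b"])
        except (TypeError, ValueError) as exc:
            raise MapLinkError(
                f"{path}: non-integer residue number on data row {row_i + 1}"
            ) from exc
        linker = str(row["linker"]) if "linker" in df.columns else "DSSO"
        if "max_dist" in df.columns and not pd.isna(row["max_dist"]):
            max_dist = float(row["max_dist"])
        else:
            max_dist = LINKER_MAX_DIST.get(linker, 35.0)
        links.append(CrossLink(str(row["protein_a"]), ra,
                               str(row["protein_b"]), rb, linker, max_dist))
    return CrossLinkSet(links, source=str(path))


def write_xl_table(xl: CrossLinkSet, path) -> None:
    pd.DataFrame(
        [
            {
                "protein_a": l.protein_a, "residue_a": l.residue_a,
                "protein_b": l.protein_b, "residue_b": l.residue_b,
                "linker": l.linker, "max_dist": l.max_dist,
            }
            for l in xl
        ]
    ).to_csv(path, index=False)


def crosslink_distance(model: AtomicModel, chain_a: str, res_a: int,
                       chain_b: str, res_b: int) -> float:
    """Euclidean Cα–Cα distance between two residues (author numbering)."""
    try:
        ia = model.atom_index(chain_a, res_a, "CA")
    except KeyError as exc:
        raise MapLinkError(f"no CA atom for residue ({chain_a!r}, {res_a})") from exc
    try:
        ib = model.atom_index(chain_b, res_b, "CA")
    except KeyError as exc:
        raise MapLinkError(f"no CA atom for residue ({chain_b!r}, {res_b})") from exc
    return float(np.linalg.norm(model.positions[ia] - model.positions[ib]))


@dataclass
class MappedLink:
    """One cross-link mapped onto a model, with all per-copy distances."""

    link: CrossLink
    chain_pairs: list        # [(chain_a, chain_b), ...]
    distances: list          # per-copy-pair distance, Å
    offset_a: int = 0
    offset_b: int = 0

    @property
    def min_distance(self) -> float:
        return min(self.distances)

    @property
    def satisfied(self) -> bool:
        return self.min_distance <= self.link.max_dist


@dataclass
class XLMappingReport:
    mapped: list = field(default_factory=list)     # MappedLink
    unmapped: list = field(default_factory=list)   # CrossLink

    @property
    def n_mapped(self) -> int:
        return len(self.mapped)

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)

    @property
    def fraction_satisfied(self) -> float:
        # vacuous truth on an empty mapped set (flagged by n_mapped == 0)
        if not self.mapped:
            return 1.0
        return sum(m.satisfied for m in self.mapped) / len(self.mapped)

    def distances(self, kind: str = None) -> np.ndarray:
        """Minimum per-link distances, optionally for one link class."""
        return np.array([
            m.min_distance for m in self.mapped
            if kind is None or m.link.kind == kind
        ])

    def summary(self) -> dict:
        out = {
            "n_mapped": self.n_mapped,
            "n_unmapped": self.n_unmapped,
            "fraction_satisfied": self.fraction_satisfied,
        }
        for kind in ("intramolecular", "intermolecular"):
            d = self.distances(kind)
            out[kind] = {
                "n": int(len(d)),
                "quantiles": (
                    {q: float(np.quantile(d, q)) for q in (0.25, 0.5, 0.75)}
                    if len(d) else {}
                ),
                "max": float(d.max()) if len(d) else None,
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.mapped:
            for (ca, cb), d in zip(m.chain_pairs, m.distances):
                rows.append({
                    "protein_a": m.link.protein_a, "residue_a": m.link.residue_a,
                    "protein_b": m.link.protein_b, "residue_b": m.link.residue_b,
                    "kind": m.link.kind, "chain_a": ca, "chain_b": cb,
                    "distance": d, "min_distance": m.min_distance,
                    "satisfied": m.satisfied, "max_dist": m.link.max_dist,
                })
        for link in self.unmapped:
            rows.append({
                "protein_a": link.protein_a, "residue_a": link.residue_a,
                "protein_b": link.protein_b, "residue_b": link.residue_b,
                "kind": link.kind, "chain_a": None, "chain_b": None,
                "distance": np.nan, "min_distance": np.nan,
                "satisfied": None, "max_dist": link.max_dist,
            })
        return pd.DataFrame(rows)

    def write(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=1)


def default_name_map(xl: CrossLinkSet, model: AtomicModel) -> dict:
    """Map protein labels to chains whose subunit label equals, or is a
    copy of (``label_copyN``), the protein label."""
    name_map = {}
    for link in xl:
        for prot in (link.protein_a, link.protein_b):
            if prot in name_map:
                continue
            chains = [
                c for c in model.chains()
                if model.subunit_map[c] == prot
                or str(model.subunit_map[c]).startswith(prot + "_copy")
            ]
            if chains:
                name_map[prot] = chains
    return name_map


def map_crosslinks(xl: CrossLinkSet, model: AtomicModel, name_map: dict = None,
                   offsets: dict = None) -> XLMappingReport:
    """Map a cross-link set onto a model and report satisfaction.

    ``name_map`` resolves protein labels to one or more chain ids (multiple
    chains express paralog/copy ambiguity); distances are computed for
    every chain-pair combination and satisfaction is judged on the minimum.
    ``offsets`` optionally adds a per-protein integer to the table's
    residue numbering. Unmapped links are listed, never dropped.
    """
    if name_map is None:
        name_map = default_name_map(xl, model)
    offsets = offsets or {}
    report = XLMappingReport()
    for link in xl:
        chains_a = name_map.get(link.protein_a, [])
        chains_b = name_map.get(link.protein_b, [])
        oa = int(offsets.get(link.protein_a, 0))
        ob = int(offsets.get(link.protein_b, 0))
        pairs, dists = [], []
        for ca in chains_a:
            for cb in chains_b:
                if ca == cb and link.kind == "intermolecular":
                    continue
                try:
                    d = crosslink_distance(model, ca, link.residue_a + oa,
                                           cb, link.residue_b + ob)
                except MapLinkError:
                    continue
                pairs.append((ca, cb))
                dists.append(d)
        if dists:
            report.mapped.append(MappedLink(link, pairs, dists, oa, ob))
        else:
            report.unmapped.append(link)
    if report.n_mapped == 0 and len(xl) > 0:
        logger.warning("no cross-link could be mapped onto the model")
    return report
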