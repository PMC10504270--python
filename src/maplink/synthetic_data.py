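"""Ground-truth fixtures: toy complexes, simulated maps, cross-link tables.

The generator builds what the pipeline's statistics assume: a rigid
multi-subunit complex with known placements, a Gaussian-simulated density
map at a stated resolution, and a cross-link table whose *true* links are
sampled comfortably under the 35 Å DSSO bound (default ≤ 30 Å, so that
satisfaction is robust to small placement error) and whose *decoys* are
sampled from pairs beyond 45 Å (an unambiguous violation band). Every
stage of fit-library generation, assembly, and validation can therefore
be tested against known ground truth without any external download.

Subunit geometry is deliberately simple — CA-only chains, either an ideal
α-helix (rise 1.5 Å/residue, radius 2.3 Å, 100°/residue twist) or a
self-avoiding random walk with 3.8 Å steps. The default is the random
walk: its irregular shapes make placements identifiable at the 6–10 Å
resolutions this pipeline targets, whereas a single straight helix is
nearly degenerate under rotation about its own axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    AtomicModel,
    DensityMap,
    MapLinkError,
    RigidTransform,
    apply_transform,
    concat_models,
    write_map,
    write_structure,
    write_transforms,
)
from .density_fit import random_rotation_matrices, simulate_map
from .xlink_restraints import CrossLink, CrossLinkSet, write_xl_table

#: average residue mass used for envelope volume targets, Da
RESIDUE_MASS = 110.0


@dataclass
class ToyComplexSpec:
    n_subunits: int = 3
    residues_per_subunit: object = 60          # int or list of ints
    geometry: str = "random_walk"              # or "ideal_helix"
    min_separation: float = 5.0                # Å between subunit CAs
    identical_copies: list = field(default_factory=list)  # groups of indices
    labels: list = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subunits < 1:
            raise MapLinkError("n_subunits must be >= 1")
        if self.min_separation < 0:
            raise MapLinkError("min_separation must be >= 0")
        if self.geometry not in ("random_walk", "ideal_helix"):
            raise MapLinkError(f"unknown geometry {self.geometry!r}")
        if isinstance(self.residues_per_subunit, int):
            self.residues_per_subunit = [self.residues_per_subunit] * self.n_subunits
        if len(self.residues_per_subunit) != self.n_subunits:
            raise MapLinkError("residues_per_subunit length mismatch")
        if self.labels is None:
            self.labels = [f"S{i + 1}" for i in range(self.n_subunits)]

    def total_mass(self) -> float:
        return RESIDUE_MASS * sum(self.residues_per_subunit)


@dataclass
class GroundTruth:
    """A toy complex with its per-subunit placements from canonical pose."""

    model: AtomicModel
    transforms: dict                  # subunit label -> RigidTransform
    canonical: dict                   # subunit label -> AtomicModel (canonical pose)
    spec: ToyComplexSpec

    def subunit_labels(self) -> list:
        return list(self.spec.labels)


def _ideal_helix(n_res: int) -> np.ndarray:
    """CA trace of an ideal α-helix: rise 1.5 Å, radius 2.3 Å, 100°/res."""
    i = np.arange(n_res)
    omega = math.radians(100.0)
    xyz = np.stack([
        2.3 * np.cos(i * omega),
        2.3 * np.sin(i * omega),
        1.5 * i,
    ], axis=1)
    return xyz - xyz.mean(axis=0)


def _self_avoiding_walk(n_res: int, rng: np.random.Generator,
                        step: float = 3.8, exclusion: float = 3.4,
                        max_tries: int = 200) -> np.ndarray:
    """Self-avoiding CA random walk with fixed 3.8 Å steps."""
    pts = [np.zeros(3)]
    for _ in range(n_res - 1):
        for attempt in range(max_tries):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = pts[-1] + step * u
            prior = np.array(pts[:-1]) if len(pts) > 1 else None
            if prior is None or np.linalg.norm(prior - cand, axis=1).min() >= exclusion:
                pts.append(cand)
                break
        else:
            raise MapLinkError("self-avoiding walk failed; try another seed")
    xyz = np.array(pts)
    return xyz - xyz.mean(axis=0)


def _canonical_subunit(spec: ToyComplexSpec, index: int,
                       rng: np.random.Generator) -> np.ndarray:
    n_res = spec.residues_per_subunit[index]
    if spec.geometry == "ideal_helix":
        return _ideal_helix(n_res)
    return _self_avoiding_walk(n_res, rng)


def _ca_model(coords: np.ndarray, chain_id: str) -> AtomicModel:
    n = len(coords)
    return AtomicModel(
        np.array([chain_id] * n, dtype=object),
        np.arange(1, n + 1),
        np.array(["ALA"] * n, dtype=object),
        np.array(["CA"] * n, dtype=object),
        np.array(["C"] * n, dtype=object),
        coords,
    )


def make_toy_complex(spec: ToyComplexSpec) -> GroundTruth:
    """Build a rigid multi-subunit complex with known placements.

    Subunits are generated in a canonical pose (identical-copy groups
    share coordinates), then placed one by one: each new subunit is
    rotated randomly and slid along a random direction until its minimum
    CA distance to the placed part of the complex falls just above
    ``min_separation``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    copy_of = {}
    for group in spec.identical_copies:
        rep = min(group)
        for idx in group:
            copy_of[idx] = rep
    canonical_coords = {}
    for i in range(spec.n_subunits):
        rep = copy_of.get(i, i)
        if rep not in canonical_coords:
            canonical_coords[rep] = _canonical_subunit(spec, rep, rng)
        canonical_coords[i] = canonical_coords[rep]

    placed = {}       # label -> world CA coords
    transforms = {}
    band = 3.0        # accepted width above min_separation, Å
    for i, label in enumerate(spec.labels):
        coords = canonical_coords[i]
        if i == 0:
            rot = random_rotation_matrices(1, rng)[0]
            tf = RigidTransform(rot, np.zeros(3))
            placed[label] = tf.apply(coords)
            transforms[label] = tf
            continue
        others = np.concatenate(list(placed.values()))
        ok = False
        for _ in range(200):
            rot = random_rotation_matrices(1, rng)[0]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rotated = coords @ rot.T
            center = others.mean(axis=0)

            def gap(s):
                pts = rotated + center + s * u
                d = np.linalg.norm(others[:, None, :] - pts[None, :, :], axis=2)
                return d.min()

            lo, hi = 0.0, 400.0
            if gap(hi) < spec.min_separation:
                continue
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if gap(mid) >= spec.min_separation:
                    hi = mid
                else:
                    lo = mid
            s = hi
            g = gap(s)
            if spec.min_separation <= g <= spec.min_separation + band:
                tf = RigidTransform(rot, center + s * u)
                placed[label] = tf.apply(coords)
                transforms[label] = tf
                ok = True
                break
        if not ok:
            raise MapLinkError(
                f"could not place subunit {label} at separation "
                f"{spec.min_separation} Å; try a different seed or larger box"
            )

    canonical_models = {
        label: _ca_model(canonical_coords[i], chr(ord("A") + i))
        for i, label in enumerate(spec.labels)
    }
    parts = [
        apply_transform(canonical_models[label], transforms[label])
        for label in spec.labels
    ]
    model = concat_models(parts, spec.labels)
    return GroundTruth(model, transforms, canonical_models, spec)


def _protein_label(subunit_label: str) -> str:
    return str(subunit_label).rsplit("_copy", 1)[0]


def simulate_crosslinks(truth: GroundTruth, n_true: int = 12,
                        decoy_fraction: float = 0.2, true_max: float = 30.0,
                        seed: int = 0, decoy_min: float = 45.0,
                        include_intra: bool = False) -> CrossLinkSet:
    """Sample a cross-link table from ground truth: true links plus decoys.

    True links are drawn uniformly from inter-subunit CA pairs at most
    ``true_max`` Å apart in ground truth (a margin below the 35 Å DSSO
    bound); ``ceil(decoy_fraction * n_true)`` decoys are drawn from pairs
    beyond ``decoy_min`` Å. Distances are evaluated as the minimum over
    identical copies, so decoys violate the bound even under copy
    ambiguity. ``include_intra`` adds intramolecular pairs (sequence
    separation ≥ 5) to the true-link pool.
    """
    rng = np.random.default_rng(seed)
    model = truth.model
    camask = model.ca_mask()
    pos = model.positions[camask]
    resnum = model.residue_numbers[camask]
    prot = np.array([_protein_label(s) for s in model.subunit_of_atoms()[camask]],
                    dtype=object)

    # candidate pairs at the protein level, distance = min over copies
    pair_dist = {}
    n = len(pos)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            pa, ra = prot[i], int(resnum[i])
            pb, rb = prot[j], int(resnum[j])
            if pa == pb:
                if not include_intra or abs(ra - rb) < 5 or ra == rb:
                    continue
            key = (pa, ra, pb, rb) if (pa, ra) <= (pb, rb) else (pb, rb, pa, ra)
            pair_dist[key] = min(pair_dist.get(key, np.inf), d[i, j])

    true_pool = sorted(k for k, v in pair_dist.items()
                       if v <= true_max and k[0] != k[2])
    if include_intra:
        true_pool = sorted(k for k, v in pair_dist.items() if v <= true_max)
    decoy_pool = sorted(k for k, v in pair_dist.items() if v > decoy_min)
    if len(true_pool) < n_true:
        raise MapLinkError(
            f"only {len(true_pool)} candidate pairs under {true_max} Å "
            f"(need {n_true})"
        )
    n_decoy = int(math.ceil(decoy_fraction * n_true))
    if len(decoy_pool) < n_decoy:
        raise MapLinkError(
            f"only {len(decoy_pool)} candidate pairs beyond {decoy_min} Å "
            f"(need {n_decoy})"
        )
    chosen_true = [true_pool[i] for i in
                   rng.choice(len(true_pool), size=n_true, replace=False)]
    chosen_decoy = [decoy_pool[i] for i in
                    rng.choice(len(decoy_pool), size=n_decoy, replace=False)]
    links, provenance = [], {}
    for key, tag in [(k, "true") for k in chosen_true] + \
                    [(k, "decoy") for k in chosen_decoy]:
        link = CrossLink(key[0], key[1], key[2], key[3], "DSSO", 35.0)
        links.append(link)
        provenance[link.key()] = tag
    return CrossLinkSet(
        links,
        source=f"simulated from ground truth (seed={seed}, n_true={n_true}, "
               f"decoy_fraction={decoy_fraction})",
        provenance=provenance,
    )


def default_bundle(seed: int = 0, resolution: float = 8.0, voxel_size: float = 2.0,
                   n_true: int = 12, decoy_fraction: float = 0.2,
                   spec: ToyComplexSpec = None, noise_sigma: float = 0.0,
                   padding: float = 12.0):
    """In-memory fixture: (truth, map, cross-link set) at the default scale
    (3 subunits × 60 residues, 8 Å map on 2 Å voxels, 12 true links + 20%
    decoys)."""
    spec = spec or ToyComplexSpec(seed=seed)
    truth = make_toy_complex(spec)
    dmap = simulate_map(truth.model, resolution, voxel_size, padding=padding)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed + 1)
        noisy = dmap.values + rng.normal(0.0, noise_sigma, size=dmap.shape)
        dmap = DensityMap(noisy, dmap.voxel_size, dmap.origin,
                          resolution_hint=dmap.resolution_hint)
    xl = simulate_crosslinks(truth, n_true=n_true, decoy_fraction=decoy_fraction,
                             seed=seed)
    return truth, dmap, xl


def make_fixture_bundle(outdir, spec: ToyComplexSpec = None,
                        resolution: float = 8.0, voxel_size: float = 2.0,
                        n_true: int = 12, decoy_fraction: float = 0.2,
                        seed: int = 0, noise_sigma: float = 0.0) -> dict:
    """Write a complete fixture bundle to ``outdir``; returns the manifest.

    Files: the ground-truth complex (mmCIF), one canonical-pose structure
    per subunit (the fitting inputs), the simulated map (MRC), the
    cross-link table (CSV), the ground-truth transforms (JSON), and a
    manifest recording the seed and parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or ToyComplexSpec(seed=seed)
    truth, dmap, xl = default_bundle(
        seed=seed, resolution=resolution, voxel_size=voxel_size,
        n_true=n_true, decoy_fraction=decoy_fraction, spec=spec,
        noise_sigma=noise_sigma,
    )
    files = {}
    write_structure(truth.model, outdir / "ground_truth.cif")
    files["ground_truth"] = "ground_truth.cif"
    for label in truth.subunit_labels():
        name = f"subunit_{label}.cif"
        write_structure(truth.canonical[label], outdir / name)
        files[f"subunit:{label}"] = name
    write_map(dmap, outdir / "map.mrc")
    files["map"] = "map.mrc"
    write_xl_table(xl, outdir / "crosslinks.csv")
    files["crosslinks"] = "crosslinks.csv"
    write_transforms(truth.transforms, outdir / "transforms.json")
    files["transforms"] = "transforms.json"
    manifest = {
        "chain_map": {
            label: chr(ord("A") + i)
            for i, label in enumerate(truth.subunit_labels())
        },
        "seed": seed,
        "resolution": resolution,
        "voxel_size": voxel_size,
        "n_true": n_true,
        "decoy_fraction": decoy_fraction,
        "noise_sigma": noise_sigma,
        "spec": {
            "n_subunits": spec.n_subunits,
            "residues_per_subunit": list(spec.residues_per_subunit),
            "geometry": spec.geometry,
            "min_separation": spec.min_separation,
            "identical_copies": [list(g) for g in spec.identical_copies],
            "labels": list(spec.labels),
            "seed": spec.seed,
        },
        "total_mass": spec.total_mass(),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
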