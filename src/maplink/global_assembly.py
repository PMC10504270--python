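"""Simultaneous multi-subunit placement over precomputed fit libraries.

Given one fit library per subunit, a target map, and a cross-link set,
the assembly stage searches the discrete configuration space (one library
candidate per subunit) by simulated-annealing Monte Carlo with Metropolis
acceptance and geometric cooling. Placements stay frozen at their
library values — moves only re-pick candidates or swap the candidates of
identical copies — matching a protocol in which alternative
configurations of pre-calculated fits are sampled.

The composite objective (lower is better) is

``total = w_cc * (1 - cc) + w_xl * sum(min((max(0, d - max_dist)/soft_scale)^2, xl_cap))
        + w_clash * n_clash``

where ``cc`` is the Pearson correlation of the combined simulated density
with the target map, ``d`` is each cross-link's Cα–Cα distance (minimum
over copies), and ``n_clash`` counts inter-subunit CA pairs closer than
``clash_cutoff``. The per-link ceiling ``xl_cap`` makes the restraint
term robust to false-positive links: a hopelessly violated link pays a
bounded penalty instead of dominating the score.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core_io import AtomicModel, DensityMap, MapLinkError, apply_transform, concat_models
from .density_fit import SIGMA_PER_RESOLUTION, _splat, atom_weights, placement_rmsd
from .xlink_restraints import CrossLinkSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreWeights:
    """Weights and constants of the composite assembly score."""

    w_cc: float = 10.0
    w_xl: float = 1.0
    w_clash: float = 0.1
    soft_scale: float = 10.0     # Å, softness of the cross-link upper bound
    clash_cutoff: float = 4.0    # Å, CA–CA excluded-volume distance
    #: per-link penalty ceiling; keeps decoy (false-positive) links from
    #: dominating the objective and dragging the assembly off the density
    xl_cap: float = 1.0


@dataclass(frozen=True)
class ScoreBreakdown:
    density_term: float
    xl_term: float
    clash_term: float
    weights: ScoreWeights = field(default_factory=ScoreWeights)

    @property
    def total(self) -> float:
        w = self.weights
        return (w.w_cc * self.density_term + w.w_xl * self.xl_term
                + w.w_clash * self.clash_term)

    def as_dict(self) -> dict:
        return {
            "density_term": self.density_term, "xl_term": self.xl_term,
            "clash_term": self.clash_term, "total": self.total,
        }


@dataclass
class AssemblyConfiguration:
    """One candidate choice per subunit, with its decomposed score."""

    choices: dict                  # subunit label -> candidate index
    score: ScoreBreakdown = None

    def index_tuple(self, order) -> tuple:
        return tuple(self.choices[s] for s in order)


@dataclass
class AnnealSchedule:
    """Simulated-annealing schedule.

    ``t_start="auto"`` calibrates the initial temperature so that about
    half of 100 random trial moves from the starting configuration would
    be accepted. Cooling is geometric per step.
    """

    t_start: object = "auto"
    cooling: float = 0.995
    n_steps: int = 10_000
    p_resample: float = 0.7
    p_swap: float = 0.2
    #: probability of a site-exchange move: two subunits jump to the
    #: candidates nearest each other's current position, undoing the
    #: exchange traps single-subunit moves cannot escape
    p_exchange: float = 0.1
    seed: int = 0
    #: fraction of resample moves drawn from the library's best-ranked
    #: candidates instead of uniformly (libraries are sorted by cc, so this
    #: exploits the precomputed single-subunit scores)
    p_top: float = 0.3
    top_k: int = 10

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise MapLinkError("cooling factor must be in (0, 1)")
        if abs(self.p_resample + self.p_swap + self.p_exchange - 1.0) > 1e-9:
            raise MapLinkError("move probabilities must sum to 1")


def copy_groups_from_labels(labels) -> list:
    """Group subunit labels of identical copies (``NAME_copyK`` convention)."""
    groups = {}
    for lab in labels:
        if "_copy" in str(lab):
            groups.setdefault(str(lab).rsplit("_copy", 1)[0], []).append(lab)
    return [g for g in groups.values() if len(g) > 1]


class AssemblyScorer:
    """Precomputed state for fast composite scoring over a fit-library space.

    Per (subunit, candidate) it caches the transformed CA coordinates, the
    candidate's simulated-density patch on the target grid, and the CA
    lookup needed by the cross-link term, so that one scoring step costs
    O(grid + links + CA pairs).
    """

    def __init__(self, libraries: dict, dmap: DensityMap, xl: CrossLinkSet,
                 weights: ScoreWeights = None, resolution: float = None,
                 name_map: dict = None):
        self.libraries = dict(libraries)
        self.order = sorted(self.libraries)
        self.dmap = dmap
        self.weights = weights or ScoreWeights()
        res = resolution or dmap.resolution_hint
        if res is None:
            raise MapLinkError("resolution needed (map carries no resolution hint)")
        self.sigma = res * SIGMA_PER_RESOLUTION
        for label, lib in self.libraries.items():
            if len(lib) == 0:
                raise MapLinkError(f"empty fit library for subunit {label!r}")
            if lib.model is None:
                raise MapLinkError(f"fit library for {label!r} has no attached model")

        t = dmap.values.astype(float).ravel()
        self._t = t
        self._St = t.sum()
        self._n = t.size
        self._denom_t = math.sqrt(max((t * t).sum() - self._St ** 2 / self._n, 0.0))

        # per-candidate caches
        self._ca = {}       # (label, idx) -> (nca, 3) transformed CA coords
        self._patch = {}    # (label, idx) -> (slices, array) density patch
        self._resnum = {}   # label -> CA residue-number -> row in CA coords
        half = int(math.ceil(4.5 * self.sigma / dmap.voxel_size))
        for label in self.order:
            lib = self.libraries[label]
            model = lib.model
            camask = model.ca_mask()
            ca = model.positions[camask] if camask.any() else model.positions
            canums = model.residue_numbers[camask] if camask.any() else model.residue_numbers
            self._resnum[label] = {int(r): i for i, r in enumerate(canums)}
            w = atom_weights(model)
            for idx, cand in enumerate(lib.candidates):
                pos = cand.transform.apply(model.positions)
                self._ca[(label, idx)] = cand.transform.apply(ca)
                self._patch[(label, idx)] = self._make_patch(pos, w, half)
        self._centroids = {
            label: np.array([
                self._ca[(label, i)].mean(axis=0)
                for i in range(len(self.libraries[label]))
            ])
            for label in self.order
        }

        self._xl_terms = self._prepare_links(xl)

    def _make_patch(self, positions, weights, half):
        vox = self.dmap.voxel_size
        idx = (positions - self.dmap.origin) / vox
        lo = np.maximum(np.floor(idx.min(axis=0)).astype(int) - half, 0)
        hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int) + half,
                        np.array(self.dmap.shape) - 1)
        if np.any(lo > hi):
            return (None, None)
        shape = tuple(hi - lo + 1)
        origin = self.dmap.origin + lo * vox
        arr = _splat(positions, weights, shape, origin, vox, self.sigma)
        slc = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
        return (slc, arr)

    def _prepare_links(self, xl: CrossLinkSet):
        """Resolve each link endpoint to (subunit label, CA row) candidates."""
        # protein label -> subunit labels (exact or NAME_copyK)
        proteins = {}
        for link in xl:
            for prot in (link.protein_a, link.protein_b):
                if prot not in proteins:
                    proteins[prot] = [
                        s for s in self.order
                        if s == prot or str(s).startswith(prot + "_copy")
                    ]
        terms = []
        for link in xl:
            ends = []
            ok = True
            for prot, res in ((link.protein_a, link.residue_a),
                              (link.protein_b, link.residue_b)):
                hits = [
                    (s, self._resnum[s][res])
                    for s in proteins[prot]
                    if res in self._resnum[s]
                ]
                if not hits:
                    ok = False
                    break
                ends.append(hits)
            if not ok:
                logger.warning("cross-link %s could not be mapped; ignored in scoring",
                               link.key())
                continue
            terms.append((ends[0], ends[1], link.max_dist))
        return terms

    # -- term evaluation ----------------------------------------------------

    def combined_values(self, choices: dict) -> np.ndarray:
        combined = np.zeros(self.dmap.shape, dtype=float)
        for label in self.order:
            slc, arr = self._patch[(label, choices[label])]
            if slc is not None:
                combined[slc] += arr
        return combined

    def density_term(self, choices: dict, combined: np.ndarray = None) -> float:
        if combined is None:
            combined = self.combined_values(choices)
        s = combined.ravel()
        ss = s.sum()
        denom_s = math.sqrt(max((s * s).sum() - ss ** 2 / self._n, 0.0))
        if denom_s == 0.0 or self._denom_t == 0.0:
            return 1.0
        cc = (np.dot(s, self._t) - ss * self._St / self._n) / (denom_s * self._denom_t)
        return 1.0 - cc

    def xl_term(self, choices: dict) -> float:
        w = self.weights
        total = 0.0
        for ends_a, ends_b, max_dist in self._xl_terms:
            dmin = np.inf
            for sa, ia in ends_a:
                pa = self._ca[(sa, choices[sa])][ia]
                for sb, ib in ends_b:
                    if sa == sb and ia == ib:
                        continue
                    pb = self._ca[(sb, choices[sb])][ib]
                    d = math.dist(pa, pb)
                    if d < dmin:
                        dmin = d
            if np.isfinite(dmin) and dmin > max_dist:
                total += min(((dmin - max_dist) / w.soft_scale) ** 2, w.xl_cap)
        return total

    def clash_term(self, choices: dict) -> float:
        cutoff = self.weights.clash_cutoff
        count = 0
        for i, a in enumerate(self.order):
            ca_a = self._ca[(a, choices[a])]
            for b in self.order[i + 1:]:
                ca_b = self._ca[(b, choices[b])]
                count += int((cdist(ca_a, ca_b) < cutoff).sum())
        return float(count)

    def score(self, choices: dict, combined: np.ndarray = None) -> ScoreBreakdown:
        return ScoreBreakdown(
            self.density_term(choices, combined),
            self.xl_term(choices),
            self.clash_term(choices),
            self.weights,
        )

    def placed_model(self, choices: dict) -> AtomicModel:
        parts, labels = [], []
        for label in self.order:
            lib = self.libraries[label]
            parts.append(apply_transform(lib.model, lib[choices[label]].transform))
            labels.append(label)
        return concat_models(parts, labels)


def composite_score(config: AssemblyConfiguration, libraries: dict, dmap: DensityMap,
                    xl: CrossLinkSet, weights: ScoreWeights = None,
                    resolution: float = None) -> ScoreBreakdown:
    """Deterministic composite score of one configuration (lower is better)."""
    scorer = AssemblyScorer(libraries, dmap, xl, weights, resolution)
    for label, idx in config.choices.items():
        if not (0 <= idx < len(libraries[label])):
            raise MapLinkError(f"invalid candidate index {idx} for subunit {label!r}")
    return scorer.score(config.choices)


def enumerate_oracle(libraries: dict, dmap: DensityMap, xl: CrossLinkSet,
                     weights: ScoreWeights = None, resolution: float = None,
                     bound: int = 10 ** 6) -> AssemblyConfiguration:
    """Exhaustive exact minimum of the composite score.

    Refuses when the configuration-space size exceeds ``bound``. Ties are
    broken toward the lexicographically smallest candidate-index tuple.
    """
    scorer = AssemblyScorer(libraries, dmap, xl, weights, resolution)
    sizes = [len(scorer.libraries[s]) for s in scorer.order]
    space = int(np.prod(sizes)) if sizes else 0
    if space > bound:
        raise MapLinkError(
            f"configuration space {space} (= {'x'.join(map(str, sizes))}) "
            f"exceeds the enumeration bound {bound}"
        )
    best = None
    for combo in itertools.product(*[range(k) for k in sizes]):
        choices = dict(zip(scorer.order, combo))
        sc = scorer.score(choices)
        if best is None or sc.total < best.score.total:
            best = AssemblyConfiguration(choices, sc)
    return best


def _calibrate_temperature(scorer, choices, sizes, rng, n_probe=100):
    """Temperature at which ~50% of random single-candidate moves accept."""
    base = scorer.score(choices).total
    ups = []
    for _ in range(n_probe):
        label = scorer.order[rng.integers(len(scorer.order))]
        if sizes[label] < 2:
            continue
        alt = dict(choices)
        new = int(rng.integers(sizes[label] - 1))
        if new >= choices[label]:
            new += 1
        alt[label] = new
        delta = scorer.score(alt).total - base
        if delta > 0:
            ups.append(delta)
    if not ups:
        return 1e-3
    return float(np.mean(ups) / math.log(2.0))


def anneal(libraries: dict, dmap: DensityMap, xl: CrossLinkSet,
           schedule: AnnealSchedule = None, weights: ScoreWeights = None,
           resolution: float = None, copy_groups: list = None,
           scorer: AssemblyScorer = None, start: dict = None):
    """Simulated-annealing Monte Carlo over the fit-library space.

    Returns ``(best_configuration, trace)`` where ``trace`` is the list of
    the current total after every accepted move. Fully reproducible for a
    fixed seed, schedule, and inputs. Ties in the best-ever configuration
    are broken toward lexicographically smaller candidate indices.
    """
    schedule = schedule or AnnealSchedule()
    if scorer is None:
        scorer = AssemblyScorer(libraries, dmap, xl, weights, resolution)
    order = scorer.order
    sizes = {s: len(scorer.libraries[s]) for s in order}
    if copy_groups is None:
        copy_groups = copy_groups_from_labels(order)
    rng = np.random.default_rng(schedule.seed)

    if start is not None:
        choices = {s: int(start[s]) for s in order}
    else:
        choices = {s: int(rng.integers(sizes[s])) for s in order}
    combined = scorer.combined_values(choices)
    current = scorer.score(choices, combined)
    t = schedule.t_start
    if t == "auto":
        t = _calibrate_temperature(scorer, choices, sizes, rng)
    t = float(t)

    best_choices, best = dict(choices), current
    trace = [current.total]
    swap_ok = bool(copy_groups) and schedule.p_swap > 0
    exchange_ok = len(order) >= 2 and schedule.p_exchange > 0
    for _ in range(schedule.n_steps):
        u = rng.random()
        if swap_ok and u < schedule.p_swap:
            group = copy_groups[rng.integers(len(copy_groups))]
            pick = rng.choice(len(group), size=2, replace=False)
            a, b = group[pick[0]], group[pick[1]]
            proposal = dict(choices)
            proposal[a], proposal[b] = choices[b], choices[a]
            changed = [a, b]
        elif exchange_ok and schedule.p_swap <= u < schedule.p_swap + schedule.p_exchange:
            pick = rng.choice(len(order), size=2, replace=False)
            a, b = order[pick[0]], order[pick[1]]
            cent_a = scorer._centroids[a][choices[a]]
            cent_b = scorer._centroids[b][choices[b]]
            new_a = int(np.argmin(
                np.linalg.norm(scorer._centroids[a] - cent_b, axis=1)))
            new_b = int(np.argmin(
                np.linalg.norm(scorer._centroids[b] - cent_a, axis=1)))
            if new_a == choices[a] and new_b == choices[b]:
                trace.append(current.total)
                t *= schedule.cooling
                continue
            proposal = dict(choices)
            proposal[a], proposal[b] = new_a, new_b
            changed = [a, b]
        else:
            label = order[int(rng.integers(len(order)))]
            if sizes[label] < 2:
                trace.append(current.total)
                t *= schedule.cooling
                continue
            if schedule.p_top > 0 and rng.random() < schedule.p_top:
                pool = min(schedule.top_k, sizes[label])
                new = int(rng.integers(pool))
                if new == choices[label]:
                    new = (new + 1) % sizes[label]
            else:
                new = int(rng.integers(sizes[label] - 1))
                if new >= choices[label]:
                    new += 1
            proposal = dict(choices)
            proposal[label] = new
            changed = [label]
        new_combined = combined.copy()
        for lab in changed:
            slc, arr = scorer._patch[(lab, choices[lab])]
            if slc is not None:
                new_combined[slc] -= arr
            slc, arr = scorer._patch[(lab, proposal[lab])]
            if slc is not None:
                new_combined[slc] += arr
        prop_score = scorer.score(proposal, new_combined)
        delta = prop_score.total - current.total
        if delta <= 0 or (t > 0 and rng.random() < math.exp(-delta / t)):
            choices, combined, current = proposal, new_combined, prop_score
            trace.append(current.total)
            tup = tuple(choices[s] for s in order)
            best_tup = tuple(best_choices[s] for s in order)
            if current.total < best.total or (
                current.total == best.total and tup < best_tup
            ):
                best_choices, best = dict(choices), current
        t *= schedule.cooling
    return AssemblyConfiguration(best_choices, best), trace


def anneal_multi(libraries: dict, dmap: DensityMap, xl: CrossLinkSet,
                 schedule: AnnealSchedule = None, weights: ScoreWeights = None,
                 resolution: float = None, n_runs: int = 5,
                 copy_groups: list = None):
    """Independent annealing runs from one base seed; returns
    ``(best_configuration, runs)`` with the lowest-total run selected.

    Multi-start selection is the standard guard against exchange traps
    (two or more subunits locked in each other's density) that
    single-subunit moves cannot escape within one run. The first run
    starts from the top-ranked candidate of every library — the
    independently best single fits, the conventional heuristic start —
    and the remaining runs start from random configurations.
    """
    schedule = schedule or AnnealSchedule()
    scorer = AssemblyScorer(libraries, dmap, xl, weights, resolution)
    runs = []
    for k in range(n_runs):
        sched_k = dataclasses.replace(schedule, seed=schedule.seed + 1000 * k)
        start = {s: 0 for s in scorer.order} if k == 0 else None
        best, _ = anneal(libraries, dmap, xl, sched_k, weights, resolution,
                         copy_groups, scorer=scorer, start=start)
        runs.append(best)
    order = scorer.order
    winner = min(runs, key=lambda r: (r.score.total, r.index_tuple(order)))
    return winner, runs


# ---------------------------------------------------------------------------
# Ensemble analysis & candidate discrimination
# ---------------------------------------------------------------------------


def ensemble_analysis(runs: list, libraries: dict, rmsd_cutoff: float = 3.0) -> dict:
    """Cluster per-subunit placements across independent runs.

    For each subunit, placements from the runs are greedily clustered by
    CA RMSD; the report gives the number of modes, their populations
    (fractions of runs), and the mean within-mode RMSD spread to the mode
    representative.
    """
    if len(runs) < 2:
        raise MapLinkError("ensemble analysis needs at least 2 runs")
    report = {}
    for label, lib in libraries.items():
        model = lib.model
        camask = model.ca_mask()
        ca = model.positions[camask] if camask.any() else model.positions
        tfs = [lib[run.choices[label]].transform for run in runs]
        modes = []   # list of [member indices]
        reps = []
        for i, tf in enumerate(tfs):
            placed = False
            for m, rep in enumerate(reps):
                if placement_rmsd(ca, tf, rep) <= rmsd_cutoff:
                    modes[m].append(i)
                    placed = True
                    break
            if not placed:
                modes.append([i])
                reps.append(tf)
        order = np.argsort([-len(m) for m in modes], kind="stable")
        entry = []
        for m in order:
            members = modes[m]
            spread = float(np.mean([
                placement_rmsd(ca, tfs[i], reps[m]) for i in members
            ]))
            entry.append({
                "population": len(members) / len(runs),
                "n_runs": len(members),
                "rmsd_spread": spread,
                "representative_run": members[0],
            })
        report[label] = {"n_modes": len(modes), "modes": entry}
    return report


def rank_candidate_models(candidates: list, dmap: DensityMap,
                          mask_radius: float = 3.0, resolution: float = None,
                          fit_config=None) -> list:
    """Rank alternative candidate models by masked map correlation.

    Candidates are either pre-placed in the map frame, or (when
    ``fit_config`` is given) best-fit first via :func:`build_fit_library`.
    Returns ``[(rank, candidate_index, cc, coverage), ...]`` best first.
    """
    from .density_fit import build_fit_library, resolve_threshold, FitSearchConfig
    from .validation_metrics import cc_mask

    if not candidates:
        raise MapLinkError("empty candidate list")
    threshold = resolve_threshold(dmap, fit_config or FitSearchConfig())
    rows = []
    for i, model in enumerate(candidates):
        placed = model
        if fit_config is not None:
            lib = build_fit_library(model, dmap, fit_config, resolution)
            if len(lib) == 0:
                rows.append((i, -1.0, 0.0))
                continue
            placed = apply_transform(model, lib[0].transform)
        cc = cc_mask(placed, dmap, mask_radius=mask_radius, resolution=resolution)
        vals = dmap.interpolate(placed.positions, fill=-np.inf)
        rows.append((i, cc, float(np.mean(vals >= threshold))))
    rows.sort(key=lambda r: -r[1])
    return [(rank + 1, i, cc, cov) for rank, (i, cc, cov) in enumerate(rows)]
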