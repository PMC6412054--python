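"""Outbreak simulation and homoplasy/recombination insertion harness.

This module reproduces the validation study behind the detector: a
discrete-time susceptible-infectious epidemic in a closed population in
which every infected individual carries a continuously mutating
nucleotide sequence inherited from their infector. Mutations follow an
infinite-sites model (each mutation event creates a brand-new alignment
column), so before any tampering every polymorphic site traces to a
single mutation event and is perfectly consistent with the true
transmission history.

Known homoplasies are then inserted by copying a clade-private allele
from one clade to a second, disjoint clade, and recombination is
emulated by overwriting a contiguous region of the recipient clade with
the donor clade's consensus. Trees are rebuilt from the tampered
alignment with neighbor joining (midpoint-rooted), and the detector's
recovery of the inserted sites is scored.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .core import _MASK_LUT, find_homoplasies
from .errors import InputError, SimulationError
from .io import Alignment, Node, PhyloTree, _collapse_unary, read_newick_string

__all__ = [
    "SimulationConfig",
    "SampledOutbreak",
    "InsertionRecord",
    "simulate_outbreak",
    "true_transmission_tree",
    "build_nj_tree",
    "nj_tree_from_distances",
    "insert_homoplasies",
    "insert_recombination",
    "run_detection_experiment",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_RESTARTS = 200
_MAX_PAIR_REDRAWS = 500


@dataclass(frozen=True)
class SimulationConfig:
    """All epidemic, mutation, sampling and insertion parameters.

    Defaults are the validation-study conditions: a population of 200,
    per-pair infectiousness 0.001 per time-step, Poisson mutation mean
    0.5 per sequence per time-step (one mutation every two steps on
    average), per-individual sampling probability 0.05 per time-step,
    and the run stops once 100 individuals have been sampled.
    ``n_inserted_homoplasies=None`` means the experiment runner draws a
    fresh uniform count in 0..100 for each replicate.
    """

    n_individuals: int = 200
    infectiousness: float = 0.001
    mutation_rate: float = 0.5
    sampling_prob: float = 0.05
    stop_after_sampled: int = 100
    n_inserted_homoplasies: int | None = None
    n_recombination_events: int = 0
    recombination_region_length: int = 100
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("infectiousness", "sampling_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.mutation_rate < 0:
            raise InputError("mutation_rate must be non-negative")
        for name in (
            "n_individuals",
            "stop_after_sampled",
            "n_recombination_events",
            "recombination_region_length",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.n_inserted_homoplasies is not None and self.n_inserted_homoplasies < 0:
            raise InputError("n_inserted_homoplasies must be non-negative")
        if self.stop_after_sampled > self.n_individuals:
            raise InputError("stop_after_sampled cannot exceed n_individuals")
        if self.n_individuals < 1:
            raise InputError("need at least one individual")


@dataclass
class SampledOutbreak:
    """The sampled sequences plus the ground truth behind them."""

    alignment: Alignment
    transmission: list[tuple[int | None, int, int]]  # (infector, infectee, time)
    samples: list[tuple[str, int, int]]  # (label, individual, sampling time)
    ancestral: str  # ancestral allele per registry site
    derived: str  # derived (mutant) allele per registry site
    n_mutation_events: int
    n_infected_steps: int
    n_restarts: int


@dataclass(frozen=True)
class InsertionRecord:
    """One inserted homoplasy or recombination event (position 1-based)."""

    position: int
    donor_tips: frozenset[str]
    recipient_tips: frozenset[str]
    kind: Literal["homoplasy", "recombination"]


def _run_epidemic(config: SimulationConfig, rng: np.random.Generator):
    """One epidemic attempt; returns None if it dies out before the
    sampling quota is reached."""
    genomes: dict[int, set[int]] = {0: set()}  # infected id -> mutated site ids
    susceptible = list(range(1, config.n_individuals))
    transmission: list[tuple[int | None, int, int]] = [(None, 0, 0)]
    sampled: list[tuple[str, int, int, frozenset[int]]] = []
    next_site = 0
    n_mut = 0
    n_inf_steps = 0
    t = 0
    while genomes and len(sampled) < config.stop_after_sampled:
        t += 1
        # transmission: each susceptible escapes all current infecteds
        # independently; on infection the donor's genome is copied
        infected_ids = list(genomes)
        if susceptible and infected_ids:
            p_inf = 1.0 - (1.0 - config.infectiousness) ** len(infected_ids)
            hits = rng.random(len(susceptible)) < p_inf
            still = []
            for s_id, hit in zip(susceptible, hits):
                if hit:
                    donor = infected_ids[rng.integers(len(infected_ids))]
                    genomes[s_id] = set(genomes[donor])
                    transmission.append((donor, s_id, t))
                else:
                    still.append(s_id)
            susceptible = still
        # mutation: every infected (including this step's infections)
        ids = list(genomes)
        n_inf_steps += len(ids)
        muts = rng.poisson(config.mutation_rate, size=len(ids))
        n_mut += int(muts.sum())
        for iid, k in zip(ids, muts):
            g = genomes[iid]
            for _ in range(int(k)):
                g.add(next_site)
                next_site += 1
        # sampling: remove and record
        draws = rng.random(len(ids))
        for iid, u in zip(ids, draws):
            if u < config.sampling_prob:
                sampled.append((f"ind{iid}_t{t}", iid, t, frozenset(genomes.pop(iid))))
                if len(sampled) >= config.stop_after_sampled:
                    break
    if len(sampled) < config.stop_after_sampled:
        return None
    return sampled, transmission, next_site, n_mut, n_inf_steps


def simulate_outbreak(config: SimulationConfig) -> SampledOutbreak:
    """Simulate one outbreak to the sampling quota, restarting with a
    fresh seed-derived stream if the epidemic dies out first."""
    for attempt in range(_MAX_RESTARTS):
        rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, attempt)))
        out = _run_epidemic(config, rng)
        if out is not None:
            sampled, transmission, n_sites, n_mut, n_steps = out
            break
    else:
        raise SimulationError(
            f"epidemic died out before {config.stop_after_sampled} samples in "
            f"{_MAX_RESTARTS} attempts"
        )
    # realise the site registry: ancestral allele uniform over ACGT,
    # derived allele uniform over the remaining three
    anc_idx = rng.integers(0, 4, size=n_sites)
    der_idx = (anc_idx + rng.integers(1, 4, size=n_sites)) % 4
    ancestral = _ACGT[anc_idx]
    derived = _ACGT[der_idx]
    records = []
    for label, _iid, _t, sites in sampled:
        row = ancestral.copy()
        if sites:
            row[np.fromiter(sites, dtype=np.int64)] = derived[
                np.fromiter(sites, dtype=np.int64)
            ]
        records.append((label, row.tobytes().decode("ascii")))
    return SampledOutbreak(
        alignment=Alignment(records),
        transmission=transmission,
        samples=[(label, iid, t) for label, iid, t, _ in sampled],
        ancestral=ancestral.tobytes().decode("ascii"),
        derived=derived.tobytes().decode("ascii"),
        n_mutation_events=n_mut,
        n_infected_steps=n_steps,
        n_restarts=attempt,
    )


def true_transmission_tree(outbreak: SampledOutbreak) -> PhyloTree:
    """The genealogy of the sampled sequences implied by the recorded
    who-infected-whom chain.

    Each individual's lineage is a time-ordered spine that branches at
    every infection it caused and terminates at its sampling tip;
    lineages that lead to no sample are pruned and unary spine nodes
    collapsed. Branch lengths are in time-steps. Because mutations
    follow the infinite-sites model, every polymorphic site in the
    clean alignment is perfectly consistent with this tree.
    """
    infections: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for donor, recipient, t in outbreak.transmission:
        if donor is not None:
            infections[donor].append((t, recipient))
    sample_of = {iid: (t, label) for label, iid, t in outbreak.samples}

    def lineage(iid: int, t0: int) -> Node | None:
        events: list[tuple[int, Node]] = []
        for t, recipient in infections[iid]:
            sub = lineage(recipient, t)
            if sub is not None:
                events.append((t, sub))
        if iid in sample_of:
            t, label = sample_of[iid]
            events.append((t, Node(label=label, length=0.0)))
        if not events:
            return None
        events.sort(key=lambda e: e[0])
        node: Node | None = None
        prev_t = 0
        for t, sub in reversed(events):
            if node is None:
                node = Node(children=[sub], length=0.0)
            else:
                node.length = float(prev_t - t)
                node = Node(children=[sub, node], length=0.0)
            prev_t = t
        node.length = float(prev_t - t0)
        return node

    root = lineage(0, 0)
    if root is None:
        raise SimulationError("no sampled individuals; cannot build a genealogy")
    return PhyloTree(_collapse_unary(root))


# ---------------------------------------------------------------------------
# tree rebuilding


def nj_tree_from_distances(labels: list[str], matrix: np.ndarray) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix, negative
    branch lengths clamped to 0, then midpoint-rooted."""
    if len(labels) < 3:
        raise InputError("neighbor joining needs at least 3 sequences")
    dm = DistanceMatrix(np.asarray(matrix, dtype=float), list(labels))
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    try:
        tree = tree.root_at_midpoint()
    except Exception:
        pass  # e.g. all-zero distances: keep the unrooted trifurcation as written
    return read_newick_string(str(tree))


def _hamming_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise count of differing sites, skipping (pairwise) any site
    where either sequence is ambiguous."""
    masks = np.stack(
        [_MASK_LUT[np.frombuffer(s.encode(), dtype=np.uint8)] for s in
         (alignment.sequences[lab] for lab in alignment.labels)]
    )
    unamb = np.isin(masks, (1, 2, 4, 8))
    n = alignment.n_sequences
    D = np.zeros((n, n))
    for i in range(n):
        diff = (masks != masks[i]) & unamb & unamb[i]
        D[i] = diff.sum(axis=1)
    return (D + D.T) / 2.0


def build_nj_tree(alignment: Alignment) -> PhyloTree:
    """Rebuild a rooted phylogeny from an alignment: pairwise Hamming
    distances, neighbor joining, midpoint rooting."""
    if alignment.n_sequences < 3:
        raise InputError("need at least 3 sequences to build a tree")
    return nj_tree_from_distances(alignment.labels, _hamming_matrix(alignment))


# ---------------------------------------------------------------------------
# homoplasy / recombination insertion


def _char_matrix(alignment: Alignment) -> np.ndarray:
    return np.stack(
        [
            np.frombuffer(alignment.sequences[lab].encode(), dtype=np.uint8)
            for lab in alignment.labels
        ]
    )


def _matrix_to_alignment(labels: list[str], matrix: np.ndarray) -> Alignment:
    return Alignment([(lab, matrix[i].tobytes().decode()) for i, lab in enumerate(labels)])


def _candidate_clades(tree: PhyloTree, row_of: dict[str, int]):
    """Internal, non-root nodes as (tip-row-index arrays, tip-label sets),
    plus the tip sets of *every* node (used for the convexity check)."""
    clades = []
    all_tipsets = set()
    for node in tree.postorder():
        tips = frozenset(t.label for t in node.postorder() if t.is_tip)
        all_tipsets.add(tips)
        if node.is_tip or node is tree.root:
            continue
        rows = np.fromiter(sorted(row_of[t] for t in tips), dtype=np.int64)
        clades.append((rows, tips))
    return clades, all_tipsets


def _draw_non_nested_pair(clades, all_tipsets, all_tips: frozenset,
                          rng: np.random.Generator,
                          require_non_separable: bool = False):
    """A random ordered pair of disjoint, non-root internal clades.

    With ``require_non_separable`` (used for homoplasy insertion) the
    union of the two tip sets must additionally not be separable by any
    single edge of the tree. Edge-separability (the union, or its
    complement, being exactly some node's clade — e.g. donor and
    recipient are sibling clades, or together cover everything) would
    let one state change explain the inserted allele, so the insertion
    would not be homoplasious on the tree it was constructed against."""
    for _ in range(_MAX_PAIR_REDRAWS):
        i, j = rng.integers(len(clades), size=2)
        if i == j:
            continue
        rows_i, tips_i = clades[i]
        rows_j, tips_j = clades[j]
        if tips_i & tips_j:
            continue
        if require_non_separable:
            union = tips_i | tips_j
            if union in all_tipsets or (all_tips - union) in all_tipsets:
                continue
        return clades[i], clades[j]
    raise SimulationError("could not draw a usable non-nested clade pair")


def _clade_private_sites(matrix: np.ndarray, donor_rows: np.ndarray) -> np.ndarray:
    """Boolean per-site vector: donor clade is monomorphic for an
    unambiguous allele that occurs nowhere outside the clade."""
    donor = matrix[donor_rows]
    mono = (donor == donor[0]).all(axis=0) & np.isin(donor[0], _ACGT)
    outside = np.delete(matrix, donor_rows, axis=0)
    absent = (outside != donor[0]).all(axis=0)
    return mono & absent


def insert_homoplasies(
    tree: PhyloTree,
    alignment: Alignment,
    count: int,
    rng: np.random.Generator,
) -> tuple[Alignment, list[InsertionRecord]]:
    """Insert ``count`` homoplasies: per insertion, a random pair of
    non-nested internal nodes (donor i, recipient j) is drawn, a site
    carrying an allele private to i's tips is selected (without
    replacement across insertions), and that allele overwrites the site
    in all of j's tips. By construction each inserted site then needs at
    least two changes on the pre-insertion tree."""
    matrix = _char_matrix(alignment)
    row_of = {lab: i for i, lab in enumerate(alignment.labels)}
    clades, all_tipsets = _candidate_clades(tree, row_of)
    all_tips = frozenset(alignment.labels)
    used = np.zeros(alignment.length, dtype=bool)
    records: list[InsertionRecord] = []
    for _ in range(count):
        placed = False
        for _ in range(_MAX_PAIR_REDRAWS):
            try:
                (donor_rows, donor_tips), (rec_rows, rec_tips) = _draw_non_nested_pair(
                    clades, all_tipsets, all_tips, rng, require_non_separable=True
                )
            except SimulationError:
                break
            eligible = _clade_private_sites(matrix, donor_rows) & ~used
            idx = np.flatnonzero(eligible)
            if idx.size == 0:
                continue
            site = int(idx[rng.integers(idx.size)])
            matrix[rec_rows, site] = matrix[donor_rows[0], site]
            used[site] = True
            records.append(
                InsertionRecord(
                    position=site + 1,
                    donor_tips=donor_tips,
                    recipient_tips=rec_tips,
                    kind="homoplasy",
                )
            )
            placed = True
            break
        if not placed:
            raise SimulationError(
                f"homoplasy insertion eligibility exhausted after {len(records)} "
                f"of {count} insertions"
            )
    return _matrix_to_alignment(alignment.labels, matrix), records


def insert_recombination(
    tree: PhyloTree,
    alignment: Alignment,
    n_events: int,
    region_length: int = 100,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Emulate ``n_events`` recombination events: per event a random
    contiguous region of ``region_length`` sites is overwritten in a
    recipient clade with the donor clade's per-site consensus (majority
    among A/C/G/T, ties broken A<C<G<T)."""
    if rng is None:
        rng = np.random.default_rng()
    if alignment.length < region_length:
        raise InputError(
            f"alignment has {alignment.length} sites, shorter than the "
            f"{region_length} bp recombination region"
        )
    matrix = _char_matrix(alignment)
    row_of = {lab: i for i, lab in enumerate(alignment.labels)}
    clades, all_tipsets = _candidate_clades(tree, row_of)
    all_tips = frozenset(alignment.labels)
    for _ in range(n_events):
        (donor_rows, _), (rec_rows, _) = _draw_non_nested_pair(
            clades, all_tipsets, all_tips, rng
        )
        start = int(rng.integers(0, alignment.length - region_length + 1))
        region = matrix[donor_rows, start : start + region_length]
        counts = np.stack([(region == b).sum(axis=0) for b in _ACGT])
        consensus = _ACGT[np.argmax(counts, axis=0)]
        informative = counts.sum(axis=0) > 0  # all-ambiguous columns keep recipient
        cols = start + np.flatnonzero(informative)
        matrix[np.ix_(rec_rows, cols)] = consensus[informative]
    return _matrix_to_alignment(alignment.labels, matrix)


# ---------------------------------------------------------------------------
# the detection experiment


@dataclass
class ExperimentSummary:
    """Replicate table plus the headline detection statistics (percent)."""

    table: pd.DataFrame
    mean_detection_pct: float
    q2_5_pct: float
    q97_5_pct: float
    n_scored: int


def _replicate_seed(master_seed: int, replicate: int) -> int:
    return int(
        np.random.SeedSequence((master_seed, replicate)).generate_state(1)[0] % (2**31)
    )


def run_detection_experiment(
    config: SimulationConfig,
    n_replicates: int,
    detect_on: Literal["rebuilt", "original"] = "rebuilt",
    tree_file: str | None = None,
) -> ExperimentSummary:
    """Run the full validation loop and score homoplasy recovery.

    Per replicate: simulate an outbreak, build an NJ tree from the clean
    alignment, insert the configured number of homoplasies (a fresh
    uniform draw in 0..100 when ``n_inserted_homoplasies`` is None),
    optionally apply recombination events, rebuild the tree from the
    modified alignment (or keep the pre-insertion tree when
    ``detect_on="original"``; or read a user-supplied tree from
    ``tree_file``, e.g. an externally computed ML tree), run detection,
    and record how many inserted positions were flagged plus how many
    flagged positions were never inserted (false positives).

    Replicates with zero insertions have no defined detection proportion
    and are excluded from the mean/quantiles, but still contribute to
    the false-positive count. Fully reproducible from ``config.rng_seed``.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be at least 1")
    rows = []
    for r in range(n_replicates):
        rep_seed = _replicate_seed(config.rng_seed, r)
        rep_config = replace(config, rng_seed=rep_seed)
        rng = np.random.default_rng(np.random.SeedSequence((rep_seed, 10**6)))
        outbreak = simulate_outbreak(rep_config)
        clean_tree = build_nj_tree(outbreak.alignment)
        k = (
            int(rng.integers(0, 101))
            if config.n_inserted_homoplasies is None
            else config.n_inserted_homoplasies
        )
        modified, inserted = insert_homoplasies(clean_tree, outbreak.alignment, k, rng)
        if config.n_recombination_events:
            modified = insert_recombination(
                clean_tree,
                modified,
                config.n_recombination_events,
                config.recombination_region_length,
                rng,
            )
        if tree_file is not None:
            from .io import read_newick

            detect_tree = read_newick(tree_file)
        elif detect_on == "original":
            detect_tree = clean_tree
        else:
            detect_tree = build_nj_tree(modified)
        result = find_homoplasies(detect_tree, modified)
        flagged = set(result.flagged_positions)
        inserted_pos = {rec.position for rec in inserted}
        detected = len(inserted_pos & flagged)
        rows.append(
            {
                "replicate": r,
                "k": k,
                "detected": detected,
                "false_positives": len(flagged - inserted_pos),
                "proportion": detected / k if k else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    scored = table["proportion"].dropna()
    return ExperimentSummary(
        table=table,
        mean_detection_pct=float(scored.mean() * 100) if len(scored) else math.nan,
        q2_5_pct=float(scored.quantile(0.025) * 100) if len(scored) else math.nan,
        q97_5_pct=float(scored.quantile(0.975) * 100) if len(scored) else math.nan,
        n_scored=int(len(scored)),
    )
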