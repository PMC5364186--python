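"""Truth-annotated synthetic small-RNA data for end-to-end validation.

The generator emulates three developmental-phase libraries of ~49-nt raw
reads: planted known and novel miRNAs (with lower-abundance miRNA* reads),
Poisson-sampled read counts from a per-library RPM design with planted
fold changes, structural-RNA fragments, polyA and adapter-only junk,
transcript degradation fragments, siRNA-like double-stranded decoy loci,
planted miRNA target sites of controlled alignment score, and a GO
annotation table with planted enriched terms.  Every planted feature is
recorded in truth tables so recovery can be measured after a blind
pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import DEFAULT_ADAPTER3
from .discover import HairpinParams, PrecursorCandidate, detect_star, evaluate_candidate
from .fold import fold_builtin
from .io import revcomp, write_fasta
from .targets import ScoringScheme, score_site

_BASES = np.array(list("ACGT"))
# sequence appended after the 3' adapter when padding reads to full length
_POST_ADAPTER_PAD = "ATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAAA"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic three-phase experiment."""

    seed: int = 7
    n_ests: int = 300
    est_length: Tuple[int, int] = (300, 800)
    n_known_mirnas: int = 50
    n_novel_precursors: int = 20
    libraries: Tuple[Tuple[str, int], ...] = (
        ("UM", 200_000),
        ("BCP", 200_000),
        ("TCP", 200_000),
    )
    n_de_mirnas: int = 12
    de_fold: float = 4.0
    known_rpm_range: Tuple[float, float] = (20.0, 5_000.0)
    de_min_rpm: float = 50.0
    novel_rpm_range: Tuple[float, float] = (300.0, 2_000.0)
    star_fraction: float = 0.1
    jitter_fraction: float = 0.1
    low_quality_fraction: float = 0.01
    contaminant_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.10,
            "tRNA": 0.05,
            "snRNA": 0.02,
            "snoRNA": 0.01,
            "repeat": 0.03,
            "exon": 0.02,
            "intron": 0.02,
            "polyA": 0.03,
            "short_junk": 0.04,
            "adapter_only": 0.02,
            "degradation": 0.06,
            "genomic": 0.50,
            "sirna": 0.01,
        }
    )
    adapter3: str = DEFAULT_ADAPTER3
    read_length: int = 49
    n_target_pairs: int = 24
    decoy_target_score: float = 4.5
    n_decoy_targets: int = 3
    n_go_terms: int = 30
    n_planted_go_terms: int = 2

    def __post_init__(self) -> None:
        fr = self.contaminant_fractions
        if any(not 0 <= f <= 1 for f in fr.values()) or sum(fr.values()) > 1:
            raise ValueError("contaminant fractions must lie in [0,1] and sum <= 1")
        if any(total < 0 for _, total in self.libraries):
            raise ValueError("library totals must be non-negative")


def make_hairpin_precursor(
    rng: np.random.Generator,
    mature_length: int = 21,
    stem_pairs: Optional[int] = None,
    loop_length: Tuple[int, int] = (6, 12),
    gu_substitutions: int = 2,
    params: HairpinParams = HairpinParams(),
) -> Tuple[str, Tuple[int, int], Tuple[int, int]]:
    """Construct a hairpin guaranteed to pass the structural criteria.

    Returns (sequence, mature interval, star-arm interval) where the
    sequence is mature + loop + (near-)reverse-complement of the mature.
    ``stem_pairs`` (default: the full mature length) is the number of
    paired mature bases; unpaired positions become symmetric internal
    loops.  Up to ``gu_substitutions`` star bases are switched to G:U
    pairings.  Raises on infeasible constraints.
    """
    stem_pairs = mature_length if stem_pairs is None else stem_pairs
    if stem_pairs < params.min_duplex_pairs:
        raise ValueError(
            f"stem_pairs {stem_pairs} below the duplex minimum {params.min_duplex_pairs}"
        )
    if stem_pairs > mature_length:
        raise ValueError("stem_pairs cannot exceed the mature length")
    n_mismatch = mature_length - stem_pairs
    if n_mismatch > params.max_duplex_bulge:
        raise ValueError("too many unpaired positions for the bulge bound")

    for _attempt in range(50):
        mature = _random_seq(rng, mature_length)
        star = list(revcomp(mature))
        # G:U substitutions: where the mature base is G, pair it with U(T)
        g_positions = [i for i, b in enumerate(mature) if b == "G"]
        rng.shuffle(g_positions)
        for i in g_positions[:gu_substitutions]:
            star[mature_length - 1 - i] = "T"
        # isolated internal mismatches, kept >= 4 nt from the stem ends
        interior = list(range(4, mature_length - 4))
        rng.shuffle(interior)
        mm_positions: List[int] = []
        for i in interior:
            if len(mm_positions) == n_mismatch:
                break
            if all(abs(i - j) > 3 for j in mm_positions):
                mm_positions.append(i)
        if len(mm_positions) < n_mismatch:
            continue
        for i in mm_positions:
            m = mature[i]
            choices = [b for b in "ACGT" if b not in (revcomp(m), m, "T" if m == "G" else "G" if m == "T" else "")]
            star[mature_length - 1 - i] = choices[int(rng.integers(len(choices)))]
        loop = _random_seq(rng, int(rng.integers(loop_length[0], loop_length[1] + 1)))
        seq = mature + loop + "".join(star)
        structure, mfe = fold_builtin(seq)
        cand = PrecursorCandidate("hairpin", 0, len(seq), "+", seq, structure, mfe)
        mature_iv = (0, mature_length)
        ok, _reasons = evaluate_candidate(cand, mature_iv, params)
        if ok:
            star_iv = (mature_length + len(loop), len(seq))
            return seq, mature_iv, star_iv
    raise ValueError("could not construct a qualifying hairpin under the constraints")


def plant_target_sites(
    ests: Dict[str, str],
    mirnas: Dict[str, str],
    target_design: Sequence[Tuple[str, str, float]],
    rng: np.random.Generator,
    scheme: ScoringScheme = ScoringScheme(),
    forbidden: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Insert target windows of exactly the intended alignment score.

    Each design row (mirna_name, est_id, intended_score) overwrites a
    window of the EST with a modified reverse complement of the miRNA
    whose optimal score under ``scheme`` equals the intended score.
    Returns the modified ESTs and a truth table.
    """
    ests = dict(ests)
    forbidden = {k: list(v) for k, v in (forbidden or {}).items()}
    rows = []
    for mirna_name, est_id, intended in target_design:
        mirna = mirnas[mirna_name]
        window = _build_scored_window(mirna, intended, scheme, rng)
        got, _ = score_site(mirna, window, scheme)
        if abs(got - intended) > 1e-9:
            raise ValueError(f"constructed window scores {got}, wanted {intended}")
        est = ests[est_id]
        L = len(window)
        spans = forbidden.setdefault(est_id, [])
        for _try in range(100):
            start = int(rng.integers(0, len(est) - L + 1))
            if all(start + L <= lo or start >= hi for lo, hi in spans):
                break
        else:
            raise ValueError(f"no room to plant a target site in {est_id}")
        ests[est_id] = est[:start] + window + est[start + L :]
        spans.append((start, start + L))
        rows.append(
            {
                "mirna": mirna_name,
                "est_id": est_id,
                "start": start,
                "end": start + L,
                "intended_score": intended,
            }
        )
    return ests, pd.DataFrame(rows)


def _build_scored_window(
    mirna: str, intended: float, scheme: ScoringScheme, rng: np.random.Generator
) -> str:
    """Modified reverse complement reaching the intended penalty exactly."""
    units = int(round(intended * 2))
    if abs(units - intended * 2) > 1e-9 or units < 0:
        raise ValueError("intended score must be a multiple of 0.5")
    L = len(mirna)
    window = list(revcomp(mirna))
    core = set(range(scheme.core_start, scheme.core_end + 1))
    # avoid terminal positions so alternative/shifted alignments stay costly
    positions = [p for p in range(2, L) if p != L]  # 1-based miRNA positions 2..L-1
    rng.shuffle(positions)
    used: Set[int] = set()

    def take(pred, n=1) -> List[int]:
        got = []
        for p in positions:
            if p in used or not pred(p):
                continue
            got.append(p)
            if len(got) == n:
                break
        return got

    def apply_mismatch(p: int) -> None:
        i = p - 1
        m = mirna[i]
        bad = {revcomp(m), "T" if m == "G" else "", "G" if m == "T" else ""}
        choices = [b for b in "ACGT" if b not in bad]
        window[L - p] = choices[int(rng.integers(len(choices)))]
        used.add(p)

    def apply_wobble(p: int) -> None:
        i = p - 1
        window[L - p] = "T" if mirna[i] == "G" else "G"
        used.add(p)

    remaining = units
    while remaining > 0:
        if remaining >= 4 and (ps := take(lambda p: p in core)):
            apply_mismatch(ps[0])
            remaining -= 4
        elif remaining >= 2 and (ps := take(lambda p: p not in core)):
            apply_mismatch(ps[0])
            remaining -= 2
        elif remaining >= 2 and (ps := take(lambda p: p in core and mirna[p - 1] in "GT")):
            apply_wobble(ps[0])
            remaining -= 2
        elif remaining == 1 and (ps := take(lambda p: p not in core and mirna[p - 1] in "GT")):
            apply_wobble(ps[0])
            remaining -= 1
        else:
            raise ValueError(f"cannot compose penalty {intended} for this miRNA")
    return "".join(window)


def make_go_annotations(
    genes: Sequence[str],
    go_design: Dict,
    rng: np.random.Generator,
) -> Tuple[Dict[str, Set[str]], pd.DataFrame]:
    """Random background GO annotation with planted enriched terms.

    ``go_design`` keys: ``n_terms``, ``planted_terms`` (list of term ids),
    ``target_genes`` (the gene set the planted terms must be enriched in),
    optional ``extra_per_planted`` (non-target genes per planted term,
    default 2).  Background genes receive 1-3 uniform terms.
    """
    n_terms = int(go_design["n_terms"])
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    planted = list(go_design.get("planted_terms", []))
    if not set(planted) <= set(terms):
        raise ValueError("planted terms must be among the generated terms")
    target_genes = sorted(go_design.get("target_genes", []))
    if planted and not target_genes:
        raise ValueError("planted enrichment requires a non-empty target gene set")
    extra = int(go_design.get("extra_per_planted", 2))
    background_terms = [t for t in terms if t not in planted]
    annotation: Dict[str, Set[str]] = {}
    for gene in genes:
        k = int(rng.integers(1, 4))
        annotation[gene] = set(rng.choice(background_terms, size=k, replace=False))
    non_targets = [g for g in genes if g not in set(target_genes)]
    for j, term in enumerate(planted):
        members = [g for i, g in enumerate(target_genes) if i % len(planted) == j]
        extras = list(rng.choice(non_targets, size=min(extra, len(non_targets)), replace=False))
        for g in members + extras:
            annotation[g].add(term)
    truth = pd.DataFrame({"term": planted, "planted": True}) if planted else pd.DataFrame(
        columns=["term", "planted"]
    )
    return annotation, truth


@dataclass
class SimulatedWorld:
    """Deterministic planted ground truth shared by all libraries."""

    config: SimulationConfig
    ests: Dict[str, str]
    known_catalog: Dict[str, str]
    refsets: Dict[str, Dict[str, str]]
    rpm_design: pd.DataFrame  # index mirna, columns libraries
    de_truth: pd.DataFrame
    novel_truth: pd.DataFrame
    target_truth: pd.DataFrame
    go_annotation: Dict[str, Set[str]]
    go_truth: pd.DataFrame
    sirna_loci: List[Tuple[str, int, int]]
    star_reads: Dict[str, str]  # mirna name -> emitted star sequence
    genome_pool: List[str] = field(default_factory=list)
    """Unassembled genomic loci: the source of the dominant unannotated
    small-RNA background that maps to no reference."""


def build_world(config: SimulationConfig) -> SimulatedWorld:
    """Generate the planted references, designs and truth tables."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lib_ids = [lib for lib, _ in config.libraries]

    # reference sets (stand-ins for the public structural/repeat databases)
    refsets = {
        "rRNA": {f"rRNA_{i}": _random_seq(rng, 600) for i in range(3)},
        "tRNA": {f"tRNA_{i}": _random_seq(rng, 75) for i in range(10)},
        "snRNA": {f"snRNA_{i}": _random_seq(rng, 150) for i in range(4)},
        "snoRNA": {f"snoRNA_{i}": _random_seq(rng, 120) for i in range(4)},
        "repeat": {f"repeat_{i}": _random_seq(rng, 400) for i in range(5)},
        "exon": {f"exon_{i}": _random_seq(rng, 500) for i in range(5)},
        "intron": {f"intron_{i}": _random_seq(rng, 500) for i in range(5)},
    }

    # known mature catalog; lengths mostly 21 nt as for conserved plant miRNAs
    lengths = rng.choice([20, 21, 22, 24], size=config.n_known_mirnas, p=[0.15, 0.55, 0.2, 0.1])
    known = {
        f"kno-miR{1000 + i}": _random_seq(rng, int(lengths[i]))
        for i in range(config.n_known_mirnas)
    }

    # ESTs with planted novel hairpins
    ests: Dict[str, str] = {}
    novel_rows = []
    star_reads: Dict[str, str] = {}
    forbidden: Dict[str, List[Tuple[int, int]]] = {}
    for i in range(config.n_ests):
        est_id = f"EST{i + 1:04d}"
        length = int(rng.integers(config.est_length[0], config.est_length[1] + 1))
        seq = _random_seq(rng, length)
        if i < config.n_novel_precursors:
            hp, (ms, me), (ss, se) = make_hairpin_precursor(rng)
            pos = int(rng.integers(120, max(121, length - len(hp) - 120)))
            seq = seq[:pos] + hp + seq[pos + len(hp) :]
            name = f"nov-miR{i + 1:02d}"
            mature = hp[ms:me]
            # star read under the Dicer 2-nt 3' overhang convention: the
            # star arm minus its first 2 nt plus the 2 nt of 3' flank
            star_arm = hp[ss:se]
            star_read = star_arm[2:] + seq[pos + len(hp) : pos + len(hp) + 2]
            star_reads[name] = star_read
            novel_rows.append(
                {
                    "name": name,
                    "est_id": est_id,
                    "start": pos,
                    "end": pos + len(hp),
                    "strand": "+",
                    "mature": mature,
                    "star_read": star_read,
                    "precursor": hp,
                    "builtin_mfe": fold_builtin(hp)[1],
                }
            )
            forbidden.setdefault(est_id, []).append((pos, pos + len(hp)))
        ests[est_id] = seq
    novel_truth = pd.DataFrame(novel_rows)

    # expression design: log-uniform RPMs, planted fold changes
    lo, hi = config.known_rpm_range
    base_known = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_known_mirnas))
    rpm = pd.DataFrame(
        {lib: base_known.copy() for lib in lib_ids}, index=list(known)
    )
    de_rows = []
    de_names = list(rng.choice(list(known), size=config.n_de_mirnas, replace=False))
    pair_cycle = [
        (lib_ids[i], lib_ids[j])
        for i in range(len(lib_ids))
        for j in range(i + 1, len(lib_ids))
    ]
    for j, name in enumerate(de_names):
        base = max(config.de_min_rpm, float(rpm.loc[name, lib_ids[0]]))
        for lib in lib_ids:
            rpm.loc[name, lib] = base
        lib_up = lib_ids[j % len(lib_ids)]
        rpm.loc[name, lib_up] = base * config.de_fold
    for name in known:
        for a, b in pair_cycle:
            ra, rb = float(rpm.loc[name, a]), float(rpm.loc[name, b])
            de_rows.append(
                {
                    "mirna": name,
                    "library_a": a,
                    "library_b": b,
                    "expected_log2fc": float(np.log2(ra / rb)),
                    "is_de": bool(abs(np.log2(ra / rb)) >= 1),
                }
            )
    de_truth = pd.DataFrame(de_rows)

    # novel expression: phase-specific patterns as seen for young miRNAs
    nlo, nhi = config.novel_rpm_range
    for row in novel_rows:
        base = float(np.exp(rng.uniform(np.log(nlo), np.log(nhi))))
        pattern = int(rng.integers(0, 3))
        phase = int(rng.integers(0, len(lib_ids)))
        vals = {}
        for k, lib in enumerate(lib_ids):
            if pattern == 0:  # all phases
                vals[lib] = base
            elif pattern == 1:  # single phase
                vals[lib] = base if k == phase else 0.0
            else:  # two phases
                vals[lib] = base if k != phase else 0.0
        rpm.loc[row["name"]] = pd.Series(vals)
    rpm_design = rpm

    # siRNA-like decoy loci (dsRNA): reads scattered on both strands
    sirna_loci = []
    for k in range(4):
        est_id = f"EST{config.n_novel_precursors + 10 + k:04d}"
        est_len = len(ests[est_id])
        start = int(rng.integers(0, est_len - 90))
        sirna_loci.append((est_id, start, start + 80))
        forbidden.setdefault(est_id, []).append((start, start + 80))

    # planted target sites for a mix of known and novel miRNAs
    target_mirnas = dict(known)
    target_mirnas.update({r["name"]: r["mature"] for r in novel_rows})
    known_pick = list(rng.choice(list(known), size=min(16, len(known)), replace=False))
    novel_pick = [r["name"] for r in novel_rows[:8]]
    pool = (known_pick + novel_pick)[: config.n_target_pairs]
    score_cycle = [0.0, 2.0, 4.0, 1.0, 3.0, 0.5]
    design = []
    target_est_ids = []
    free_ests = [f"EST{i + 1:04d}" for i in range(config.n_novel_precursors + 20, config.n_ests)]
    for j, name in enumerate(pool):
        est_id = free_ests[j % len(free_ests)]
        design.append((name, est_id, score_cycle[j % len(score_cycle)]))
        target_est_ids.append(est_id)
    for j in range(config.n_decoy_targets):
        name = pool[j]
        est_id = free_ests[(len(pool) + j) % len(free_ests)]
        design.append((name, est_id, config.decoy_target_score))
    ests, target_truth = plant_target_sites(
        ests, target_mirnas, design, rng, forbidden=forbidden
    )

    # GO annotation with terms enriched in the sub-threshold target genes
    true_target_genes = set(
        target_truth.loc[target_truth["intended_score"] <= ScoringScheme().max_score, "est_id"]
    )
    planted_terms = [f"GO:{i:07d}" for i in range(1, config.n_planted_go_terms + 1)]
    go_annotation, go_truth = make_go_annotations(
        list(ests),
        {
            "n_terms": config.n_go_terms,
            "planted_terms": planted_terms,
            "target_genes": true_target_genes,
        },
        rng,
    )

    genome_pool = [_random_seq(rng, 500) for _ in range(400)]

    return SimulatedWorld(
        config=config,
        ests=ests,
        known_catalog=known,
        refsets=refsets,
        rpm_design=rpm_design,
        de_truth=de_truth,
        novel_truth=novel_truth,
        target_truth=target_truth,
        go_annotation=go_annotation,
        go_truth=go_truth,
        sirna_loci=sirna_loci,
        star_reads=star_reads,
        genome_pool=genome_pool,
    )


def _finish_read(insert: str, adapter3: str, read_length: int) -> str:
    raw = insert + adapter3 + _POST_ADAPTER_PAD
    while len(raw) < read_length:
        raw += _POST_ADAPTER_PAD
    return raw[:read_length]


def simulate_library(
    world: SimulatedWorld, library_id: str
) -> List[Tuple[str, str, str]]:
    """Generate the raw reads of one library: (read_id, sequence, quality).

    Counts per planted miRNA are Poisson with mean rpm x total / 1e6;
    mature reads carry a 1-nt 3' jitter at the configured fraction; star
    reads appear at ``star_fraction`` of the mature abundance; contaminant
    classes are emitted at their configured fractions.  Deterministic per
    (seed, library).
    """
    config = world.config
    lib_ids = [lib for lib, _ in config.libraries]
    if library_id not in lib_ids:
        raise KeyError(f"unknown library {library_id!r}")
    lib_index = lib_ids.index(library_id)
    total = dict(config.libraries)[library_id]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1 + lib_index]))
    reads: List[str] = []
    if total == 0:
        return []

    def emit(insert: str, n: int) -> None:
        reads.extend([insert] * n)

    # planted miRNAs (known + novel) and their stars
    matures = dict(world.known_catalog)
    matures.update(dict(zip(world.novel_truth["name"], world.novel_truth["mature"])))
    for name, mature in matures.items():
        mean = float(world.rpm_design.loc[name, library_id]) * total / 1e6
        if mean <= 0:
            continue
        k = int(rng.poisson(mean))
        n_jitter = int(rng.binomial(k, config.jitter_fraction)) if k else 0
        emit(mature, k - n_jitter)
        for _ in range(n_jitter):
            if rng.random() < 0.5 and len(mature) > 18:
                emit(mature[:-1], 1)
            else:
                emit(mature + str(rng.choice(_BASES)), 1)
        star = world.star_reads.get(name)
        if star:
            emit(star, int(rng.poisson(mean * config.star_fraction)))

    fr = config.contaminant_fractions
    # fragment length distribution: 24-nt mode, 21-nt shoulder, as for
    # plant heterochromatic siRNAs and degradation products
    frag_lengths = np.arange(18, 31)
    frag_w = np.array([2, 2, 2, 6, 5, 5, 12, 3, 2, 2, 2, 2, 2], dtype=float)
    frag_w /= frag_w.sum()

    def emit_fragments(sources: List[str], n: int, sense_fraction: float) -> None:
        if n <= 0 or not sources:
            return
        lens = rng.choice(frag_lengths, size=n, p=frag_w)
        picks = rng.integers(0, len(sources), size=n)
        flips = rng.random(size=n) >= sense_fraction
        for ln, pick, flip in zip(lens, picks, flips):
            src = sources[pick]
            if len(src) <= ln:
                continue
            p = int(rng.integers(0, len(src) - ln))
            frag = src[p : p + int(ln)]
            emit(revcomp(frag) if flip else frag, 1)

    # reference-derived fragments (structural RNAs, repeats, exons, introns)
    for cat in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron"):
        emit_fragments(
            list(world.refsets[cat].values()),
            int(rng.poisson(fr.get(cat, 0) * total)),
            sense_fraction=0.85,
        )
    # polyA
    for _ in range(int(rng.poisson(fr.get("polyA", 0) * total))):
        emit("A" * int(rng.integers(18, 31)), 1)
    # short junk (discarded as < 18 nt after trimming)
    for _ in range(int(rng.poisson(fr.get("short_junk", 0) * total))):
        emit(_random_seq(rng, int(rng.integers(8, 18))), 1)
    # adapter-only
    emit("", int(rng.poisson(fr.get("adapter_only", 0) * total)))
    # transcript degradation fragments over the ESTs (mostly sense strand)
    emit_fragments(
        list(world.ests.values()),
        int(rng.poisson(fr.get("degradation", 0) * total)),
        sense_fraction=0.85,
    )
    # the dominant unannotated background: fragments of genomic loci that
    # are absent from every reference set and from the EST assembly
    emit_fragments(
        world.genome_pool,
        int(rng.poisson(fr.get("genomic", 0) * total)),
        sense_fraction=0.5,
    )
    # siRNA-like loci: balanced plus/minus coverage across a span
    n_sirna = int(rng.poisson(fr.get("sirna", 0) * total))
    for _ in range(n_sirna):
        est_id, lo, hi = world.sirna_loci[int(rng.integers(len(world.sirna_loci)))]
        est = world.ests[est_id]
        ln = int(rng.integers(20, 25))
        p = int(rng.integers(lo, max(lo + 1, hi - ln)))
        frag = est[p : p + ln]
        emit(frag if rng.random() < 0.5 else revcomp(frag), 1)

    order = rng.permutation(len(reads))
    out = []
    good_q = "I" * config.read_length
    bad_q = "#" * config.read_length
    for idx, j in enumerate(order):
        raw = _finish_read(reads[j], config.adapter3, config.read_length)
        qual = bad_q if rng.random() < config.low_quality_fraction else good_q
        out.append((f"{library_id}_{idx + 1}", raw, qual))
    return out


def simulate(config: SimulationConfig, outdir: str | Path) -> SimulatedWorld:
    """Write the full synthetic experiment to ``outdir``.

    Emits one FASTQ per library, per-category reference FASTAs, the EST
    FASTA, the GO annotation TSV, truth tables and a config snapshot.
    Identical configs (including seed) produce byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "refs").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    world = build_world(config)

    for lib, _total in config.libraries:
        with open(outdir / f"{lib}.fastq", "w") as fh:
            for read_id, seq, qual in simulate_library(world, lib):
                fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")

    write_fasta(world.ests, outdir / "ests.fa")
    for cat, records in world.refsets.items():
        write_fasta(records, outdir / "refs" / f"{cat}.fa")
    write_fasta(world.known_catalog, outdir / "refs" / "known_mirnas.fa")

    go_rows = []
    for gene in sorted(world.go_annotation):
        for term in sorted(world.go_annotation[gene]):
            go_rows.append({"gene": gene, "go_id": term, "namespace": "biological_process",
                            "term_name": f"synthetic term {term[-4:]}"})
    pd.DataFrame(go_rows).to_csv(outdir / "go_annotation.tsv", sep="\t", index=False)

    world.novel_truth.to_csv(outdir / "truth" / "novel_mirnas.tsv", sep="\t", index=False)
    world.rpm_design.rename_axis("mirna").to_csv(outdir / "truth" / "rpm_design.tsv", sep="\t")
    world.de_truth.to_csv(outdir / "truth" / "de.tsv", sep="\t", index=False)
    world.target_truth.to_csv(outdir / "truth" / "targets.tsv", sep="\t", index=False)
    world.go_truth.to_csv(outdir / "truth" / "go_terms.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return world
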