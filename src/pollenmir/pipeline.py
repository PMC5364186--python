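"""End-to-end orchestration of the small-RNA analysis stages.

``run_all`` executes preprocess -> annotate -> discover -> de -> targets
-> go, each stage consuming the previous stage's outputs, with
per-stage caching keyed on input checksums: rerunning with unchanged
inputs skips completed stages and reproduces identical reports.
Internally all coordinates are 0-based half-open; GFF3 output is written
1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import DEFAULT_ADAPTER3
from .annotate import (
    KnownMiRNACatalog,
    ReferenceSet,
    annotate_reads,
    build_count_matrix,
)
from .discover import HairpinParams, discover_novel
from .enrich import enrich_terms
from .io import iter_fastq, read_collapsed_fasta, read_fasta, write_collapsed_fasta
from .preprocess import merge_libraries, preprocess_library
from .quantify import (
    classify_abundance,
    classify_trend,
    cluster_profiles,
    differential_expression,
    expression_profile_matrix,
    normalize_rpm,
)
from .targets import ScoringScheme, scan_many

logger = logging.getLogger("pollenmir")

_STAGES = ("preprocess", "annotate", "discover", "de", "targets", "go")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def manifest_from_simulation(simdir: str | Path) -> Dict:
    """Input manifest for a directory written by :func:`simdata.simulate`."""
    simdir = Path(simdir)
    import yaml

    config = yaml.safe_load((simdir / "config.yaml").read_text())
    libs = [lib for lib, _ in config["libraries"]]
    return {
        "libraries": {lib: str(simdir / f"{lib}.fastq") for lib in libs},
        "adapter3": config["adapter3"],
        "refs": {
            cat: str(simdir / "refs" / f"{cat}.fa")
            for cat in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")
        },
        "known_mirnas": str(simdir / "refs" / "known_mirnas.fa"),
        "ests": str(simdir / "ests.fa"),
        "go_annotation": str(simdir / "go_annotation.tsv"),
        "pairs": [[a, b] for i, a in enumerate(libs) for b in libs[i + 1 :]],
    }


def _hash_inputs(paths: Sequence[str | Path], extra: str = "") -> str:
    h = hashlib.sha256(extra.encode())
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    return h.hexdigest()


class _Cache:
    def __init__(self, outdir: Path) -> None:
        self.path = outdir / "manifest.json"
        self.data: Dict = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, inputs_hash: str, outputs: Sequence[Path]) -> bool:
        rec = self.data.get(stage)
        return (
            rec is not None
            and rec.get("inputs_hash") == inputs_hash
            and all(Path(p).exists() for p in rec.get("outputs", []))
            and {str(p) for p in outputs} <= set(rec.get("outputs", []))
        )

    def record(self, stage: str, inputs_hash: str, outputs: Sequence[Path]) -> None:
        self.data[stage] = {
            "inputs_hash": inputs_hash,
            "outputs": sorted(str(p) for p in outputs),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_all(
    inputs: Dict,
    outdir: str | Path,
    hairpin_params: HairpinParams = HairpinParams(),
    scheme: ScoringScheme = ScoringScheme(),
    lfc: float = 1.0,
    alpha: float = 0.05,
    cluster_k: int = 6,
    engine: str = "builtin",
    min_seed_count: int = 5,
) -> Dict[str, pd.DataFrame]:
    """Run the full pipeline; returns the key report tables.

    ``inputs`` is a manifest dict with keys ``libraries`` (id -> FASTQ),
    ``adapter3``, ``refs`` (category -> FASTA), ``known_mirnas``,
    ``ests``, ``go_annotation`` and ``pairs``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(outdir)
    libs: Dict[str, str] = dict(inputs["libraries"])
    lib_ids = list(libs)
    adapter3 = inputs.get("adapter3", DEFAULT_ADAPTER3)
    pairs: List[Tuple[str, str]] = [tuple(p) for p in inputs.get(
        "pairs", [[a, b] for i, a in enumerate(lib_ids) for b in lib_ids[i + 1 :]]
    )]

    # ---------------- preprocess ----------------
    pre_dir = outdir / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    stats_path = pre_dir / "stats.tsv"
    collapsed_paths = {lib: pre_dir / f"{lib}.collapsed.fa" for lib in lib_ids}
    try:
        pre_hash = _hash_inputs(list(libs.values()), extra=adapter3)
    except FileNotFoundError as exc:
        raise StageError("preprocess", f"missing input {exc}") from exc
    pre_outputs = [stats_path, *collapsed_paths.values()]
    if not cache.fresh("preprocess", pre_hash, pre_outputs):
        logger.info("[preprocess] trimming and collapsing %d libraries", len(libs))
        stat_rows = []
        for lib, fastq in libs.items():
            counts, stats = preprocess_library(iter_fastq(fastq), adapter3)
            if stats.raw_count == 0:
                raise StageError("preprocess", f"library {lib} is empty: {fastq}")
            write_collapsed_fasta(counts, collapsed_paths[lib])
            stat_rows.append(
                {
                    "library": lib,
                    "raw_count": stats.raw_count,
                    "clean_count": stats.clean_count,
                    "unique_count": stats.unique_count,
                    **{f"len_{k}": v for k, v in sorted(stats.length_histogram.items())},
                    **{f"discard_{k}": v for k, v in sorted(stats.discarded.items())},
                }
            )
        pd.DataFrame(stat_rows).fillna(0).to_csv(stats_path, sep="\t", index=False)
        cache.record("preprocess", pre_hash, pre_outputs)
    stats_df = pd.read_csv(stats_path, sep="\t").set_index("library")
    totals = {lib: int(stats_df.loc[lib, "clean_count"]) for lib in lib_ids}
    unique_reads = merge_libraries(
        {lib: read_collapsed_fasta(p) for lib, p in collapsed_paths.items()}
    )

    # ---------------- annotate ----------------
    ann_dir = outdir / "annotate"
    ann_dir.mkdir(exist_ok=True)
    ann_path = ann_dir / "annotation.tsv"
    counts_path = ann_dir / "counts.tsv"
    ref_paths = dict(inputs.get("refs", {}))
    try:
        ann_hash = _hash_inputs(
            [*collapsed_paths.values(), *ref_paths.values(), inputs["known_mirnas"]]
        )
    except FileNotFoundError as exc:
        raise StageError("annotate", f"missing input {exc}") from exc
    if not cache.fresh("annotate", ann_hash, [ann_path, counts_path]):
        logger.info("[annotate] %d unique reads", len(unique_reads))
        refsets = [
            ReferenceSet.from_records(cat, read_fasta(path).items())
            for cat, path in ref_paths.items()
        ]
        catalog = KnownMiRNACatalog.from_records(read_fasta(inputs["known_mirnas"]).items())
        refsets.append(ReferenceSet("known_miRNA", dict(catalog.entries)))
        records = annotate_reads(list(unique_reads), refsets)
        ann_df = pd.DataFrame(
            {
                "sequence": [r.sequence for r in records],
                "category": [r.category for r in records],
                "hit_id": [r.hit_id for r in records],
                **{
                    lib: [unique_reads[r.sequence].get(lib, 0) for r in records]
                    for lib in lib_ids
                },
            }
        )
        ann_df.to_csv(ann_path, sep="\t", index=False)
        mirna_reads = {
            r.sequence: unique_reads[r.sequence]
            for r in records
            if r.category == "known_miRNA"
        }
        counts = build_count_matrix(mirna_reads, catalog, lib_ids)
        counts.to_csv(counts_path, sep="\t")
        cache.record("annotate", ann_hash, [ann_path, counts_path])
    ann_df = pd.read_csv(ann_path, sep="\t")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)

    # ---------------- discover ----------------
    disc_dir = outdir / "discover"
    disc_dir.mkdir(exist_ok=True)
    novel_path = disc_dir / "novel_mirnas.tsv"
    prec_fa = disc_dir / "precursors.fa"
    prec_gff = disc_dir / "precursors.gff3"
    struct_path = disc_dir / "structures.txt"
    try:
        disc_hash = _hash_inputs([ann_path, inputs["ests"]], extra=f"{engine}:{min_seed_count}")
    except FileNotFoundError as exc:
        raise StageError("discover", f"missing input {exc}") from exc
    disc_outputs = [novel_path, prec_fa, prec_gff, struct_path]
    if not cache.fresh("discover", disc_hash, disc_outputs):
        candidates = {
            row.sequence: unique_reads[row.sequence]
            for row in ann_df.itertuples()
            if row.category in ("unannotated", "intron")
        }
        logger.info("[discover] %d candidate reads", len(candidates))
        ests = read_fasta(inputs["ests"])
        novels = discover_novel(
            candidates,
            ests,
            all_reads=unique_reads,
            params=hairpin_params,
            engine=engine,
            min_seed_count=min_seed_count,
        )
        passed = [n for n in novels if n.passed]
        rows = []
        with open(prec_fa, "w") as fa, open(prec_gff, "w") as gff, open(
            struct_path, "w"
        ) as st:
            gff.write("##gff-version 3\n")
            for i, n in enumerate(passed, start=1):
                name = f"nov-cand{i:02d}"
                p = n.precursor
                rows.append(
                    {
                        "name": name,
                        "mature": n.mature,
                        "star": n.star.sequence if n.star else "",
                        "star_observed": bool(n.star and n.star.observed),
                        "est_id": p.source_id,
                        "start": p.start,
                        "end": p.end,
                        "strand": p.strand,
                        "mfe": p.mfe,
                        **{f"count_{lib}": n.read_support.get(lib, 0) for lib in lib_ids},
                        **{
                            f"star_count_{lib}": n.star_support.get(lib, 0)
                            for lib in lib_ids
                        },
                    }
                )
                fa.write(f">{name}\n{p.sequence}\n")
                gff.write(
                    f"{p.source_id}\tpollenmir\tmiRNA_primary_transcript\t"
                    f"{p.start + 1}\t{p.end}\t.\t{p.strand}\t.\tID={name}\n"
                )
                st.write(f">{name}\n{p.sequence}\n{p.structure} ({p.mfe:.1f})\n")
        pd.DataFrame(
            rows,
            columns=[
                "name", "mature", "star", "star_observed", "est_id", "start", "end",
                "strand", "mfe",
                *[f"count_{lib}" for lib in lib_ids],
                *[f"star_count_{lib}" for lib in lib_ids],
            ],
        ).to_csv(novel_path, sep="\t", index=False)
        cache.record("discover", disc_hash, disc_outputs)
    novel_df = pd.read_csv(novel_path, sep="\t")

    # ---------------- differential expression ----------------
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    de_path = de_dir / "de_report.tsv"
    prof_path = de_dir / "profiles.tsv"
    groups_path = de_dir / "groups.tsv"
    de_hash = _hash_inputs([counts_path, novel_path, stats_path], extra=f"{lfc}:{alpha}:{cluster_k}")
    de_outputs = [de_path, prof_path, groups_path]
    if not cache.fresh("de", de_hash, de_outputs):
        logger.info("[de] %d known + %d novel miRNAs", len(counts), len(novel_df))
        novel_counts = pd.DataFrame(
            {lib: novel_df[f"count_{lib}"].tolist() for lib in lib_ids},
            index=novel_df["name"],
        ) if len(novel_df) else pd.DataFrame(columns=lib_ids)
        all_counts = pd.concat([counts, novel_counts]) if len(novel_counts) else counts
        de_df = differential_expression(all_counts, totals, pairs, lfc=lfc, alpha=alpha)
        # per-miRNA abundance tier and (for three phases) trend class
        tiers = {
            m: classify_abundance(int(all_counts.loc[m].max())) for m in all_counts.index
        }
        de_df["tier"] = de_df["mirna"].map(tiers)
        if len(lib_ids) == 3:
            trends = {
                m: classify_trend(
                    *[normalize_rpm(int(all_counts.loc[m, lib]), totals[lib]) for lib in lib_ids]
                )
                for m in all_counts.index
            }
            de_df["trend"] = de_df["mirna"].map(trends)
        de_df.to_csv(de_path, sep="\t", index=False)
        profiles = expression_profile_matrix(all_counts, totals, pairs)
        profiles.to_csv(prof_path, sep="\t")
        if len(profiles) >= 2:
            _, groups = cluster_profiles(profiles, k=min(cluster_k, len(profiles)))
            groups.rename_axis("mirna").to_csv(groups_path, sep="\t")
        else:
            pd.Series(dtype=int, name="group").rename_axis("mirna").to_csv(
                groups_path, sep="\t"
            )
        cache.record("de", de_hash, de_outputs)
    de_df = pd.read_csv(de_path, sep="\t")

    # ---------------- targets ----------------
    tgt_dir = outdir / "targets"
    tgt_dir.mkdir(exist_ok=True)
    tgt_path = tgt_dir / "targets.tsv"
    tgt_hash = _hash_inputs(
        [inputs["known_mirnas"], inputs["ests"], novel_path], extra=str(scheme)
    )
    if not cache.fresh("targets", tgt_hash, [tgt_path]):
        mirnas = dict(read_fasta(inputs["known_mirnas"]))
        for row in novel_df.itertuples():
            mirnas[row.name] = row.mature
        ests = read_fasta(inputs["ests"])
        logger.info("[targets] scanning %d miRNAs x %d ESTs", len(mirnas), len(ests))
        sites = scan_many(mirnas, ests, scheme)
        # a hairpin is self-complementary: mask each novel miRNA's own locus
        own_loci = {
            row.name: (row.est_id, int(row.start), int(row.end))
            for row in novel_df.itertuples()
        }
        sites = [
            s
            for s in sites
            if not (
                s.mirna in own_loci
                and s.est_id == own_loci[s.mirna][0]
                and s.start < own_loci[s.mirna][2]
                and s.end > own_loci[s.mirna][1]
            )
        ]
        tgt_df = pd.DataFrame(
            [
                {
                    "mirna": s.mirna,
                    "est_id": s.est_id,
                    "start": s.start,
                    "end": s.end,
                    "score": s.score,
                    "alignment_mirna_3to5": s.alignment.lines()[0],
                    "alignment_match": s.alignment.lines()[1],
                    "alignment_target_5to3": s.alignment.lines()[2],
                    "cleavage_10": s.cleavage_positions[0] if s.cleavage_positions else "",
                    "cleavage_11": s.cleavage_positions[1] if s.cleavage_positions else "",
                }
                for s in sites
            ],
            columns=[
                "mirna", "est_id", "start", "end", "score", "alignment_mirna_3to5",
                "alignment_match", "alignment_target_5to3", "cleavage_10", "cleavage_11",
            ],
        )
        tgt_df.to_csv(tgt_path, sep="\t", index=False)
        cache.record("targets", tgt_hash, [tgt_path])
    tgt_df = pd.read_csv(tgt_path, sep="\t")

    # ---------------- GO enrichment ----------------
    go_dir = outdir / "go"
    go_dir.mkdir(exist_ok=True)
    go_path = go_dir / "go_enrichment.tsv"
    try:
        go_hash = _hash_inputs([inputs["go_annotation"], tgt_path, inputs["ests"]])
    except FileNotFoundError as exc:
        raise StageError("go", f"missing input {exc}") from exc
    if not cache.fresh("go", go_hash, [go_path]):
        go_table = pd.read_csv(inputs["go_annotation"], sep="\t")
        annotation: Dict[str, set] = {}
        for row in go_table.itertuples():
            annotation.setdefault(row.gene, set()).add(row.go_id)
        background = set(read_fasta(inputs["ests"]))
        target_genes = set(tgt_df["est_id"])
        if target_genes:
            go_df = enrich_terms(target_genes, annotation, background, alpha=alpha)
        else:
            go_df = pd.DataFrame(
                columns=["term", "N", "n", "M", "m", "p_raw", "enrichment_as_printed",
                         "enrichment_conventional", "p_bonf", "significant"]
            )
        go_df.to_csv(go_path, sep="\t", index=False)
        cache.record("go", go_hash, [go_path])
    go_df = pd.read_csv(go_path, sep="\t")

    logger.info("[done] reports in %s", outdir)
    return {
        "stats": stats_df.reset_index(),
        "annotation": ann_df,
        "counts": counts,
        "novel": novel_df,
        "de": de_df,
        "targets": tgt_df,
        "go": go_df,
    }
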