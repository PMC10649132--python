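"""End-to-end orchestration: filter -> train -> classify -> de -> targets -> report.

Each stage writes its outputs into a run directory which is append-only for
the duration of the run; a provenance manifest records the seed, the config
and SHA-256 checksums of every artifact.  Reruns with the same config and
seed are byte-identical (no timestamps enter any output).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coding, de, filtering, formats, targets
from .models import CountMatrix, SequenceRecord, TranscriptModel

logger = logging.getLogger("lncpipe")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults are the study's published constants."""

    min_length: int = 200
    min_exons: int = 2
    orf_threshold: int = 300
    evalue_threshold: float = 1e-5
    n_folds: int = 10
    coding_probability_threshold: float = 0.5
    alpha: float = 0.05
    lfc: float = 1.0
    r_min: float = 0.90
    cis_window: int = 20_000
    seed: int = 0
    exclude_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("min_length", "min_exons", "orf_threshold", "n_folds",
                     "cis_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("evalue_threshold", "alpha", "lfc", "r_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    outdir: Path
    candidate_set: object
    novel_lncRNAs: list[str]
    annotated_lncRNAs: list[str]
    de_genes: pd.DataFrame
    de_lnc: pd.DataFrame
    edges: list
    manifest: dict = field(default_factory=dict)


def identify_lncRNAs(queries: list[TranscriptModel],
                     query_seqs: dict[str, str],
                     reference: list[TranscriptModel],
                     ref_seqs: dict[str, str],
                     config: PipelineConfig,
                     hits=None) -> dict:
    """The full lncRNA identification cascade on in-memory objects.

    Returns a dict with the candidate set, class codes, trained model,
    novel/annotated lncRNA ids and the cumulative removal log by stage.
    """
    cascade, codes = filtering.run_cascade(
        queries, query_seqs, reference,
        min_length=config.min_length, min_exons=config.min_exons)
    removal = {tid: ("cascade", reason)
               for tid, reason in cascade.removal_log.items()}

    # training data: reference transcripts by biotype, deduplicated
    train_records = [SequenceRecord(t.transcript_id, ref_seqs[t.transcript_id])
                     for t in reference
                     if t.biotype in ("protein_coding", "lncRNA")]
    train_records, _dups = filtering.deduplicate(train_records)
    biotype = {t.transcript_id: t.biotype for t in reference}
    labels = ["coding" if biotype[r.id] == "protein_coding" else "noncoding"
              for r in train_records]
    coding_seqs = [r.sequence for r, l in zip(train_records, labels) if l == "coding"]
    noncoding_seqs = [r.sequence for r, l in zip(train_records, labels)
                      if l == "noncoding"]
    table = coding.build_hexamer_table(coding_seqs, noncoding_seqs)
    X_train = coding.feature_matrix(train_records, table)
    model = coding.train_classifier(X_train, labels, n_folds=config.n_folds,
                                    seed=config.seed)

    # candidate flow: ORF filter -> classifier -> homology triage
    candidates, rm_orf = coding.orf_filter(
        cascade.novel_candidates, query_seqs, threshold=config.orf_threshold)
    removal.update({t: ("orf_filter", r) for t, r in rm_orf.items()})

    feats = np.vstack([coding.extract_features(query_seqs[t], table)
                       for t in candidates]) if candidates else np.empty((0, 6))
    candidates, rm_pred, probs = coding.predict_noncoding(
        model, feats, candidates, threshold=config.coding_probability_threshold)
    removal.update({t: ("classifier", r) for t, r in rm_pred.items()})

    groups = coding.triage_by_homology(candidates, hits or [],
                                       evalue_threshold=config.evalue_threshold)
    novel = [t for t in candidates if groups[t] in (2, 3)]
    removal.update({t: ("homology", "group1_coding_match")
                    for t in candidates if groups[t] == 1})

    return {
        "cascade": cascade,
        "class_codes": codes,
        "model": model,
        "hexamer_table": table,
        "novel_lncRNAs": novel,
        "annotated_lncRNAs": list(cascade.annotated_lncRNAs),
        "homology_groups": groups,
        "coding_probability": probs,
        "removal_log": removal,
    }


def score_identification(novel_called: list[str], truth) -> dict[str, float]:
    """Sensitivity/contamination of novel-lncRNA calls against planted truth.

    A planted noncoding transcript counts as recovered if it or any of its
    byte-identical duplicates survives (dedup keeps exactly one of each
    group, under whichever id sorts first).
    """
    novel = set(novel_called)
    dup_of = truth.planted_duplicates
    twins: dict[str, set[str]] = {}
    for dup, orig in dup_of.items():
        twins.setdefault(orig, set()).add(dup)
    planted_nc = [t for t, lab in truth.assembled_label.items()
                  if lab == "noncoding"
                  and truth.planted_class_code[t] in "joxiu"
                  and t not in dup_of]
    recovered = sum(1 for t in planted_nc
                    if t in novel or (twins.get(t, set()) & novel))
    contam = sum(1 for t in novel if truth.assembled_label[t] == "coding")
    return {
        "n_planted_noncoding": len(planted_nc),
        "sensitivity": recovered / len(planted_nc) if planted_nc else float("nan"),
        "n_called": len(novel),
        "contamination": contam / len(novel) if novel else 0.0,
    }


def run_de_split(matrix: CountMatrix, lnc_genes: set[str],
                 config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE with one shared normalization/test pass, BH applied separately to
    the gene (coding/other) and lncRNA families."""
    if config.exclude_samples:
        matrix = matrix.drop_samples(list(config.exclude_samples))
    X = matrix.counts.to_numpy(dtype=float)
    factors = de.size_factors(X)
    samples = matrix.sample_ids
    group_idx = [
        np.array([i for i, s in enumerate(samples) if matrix.groups[s] == g])
        for g in ("control", "treated")
    ]
    disp = de.estimate_dispersion(X, factors, group_idx)
    res = de.wald_test(matrix, factors, disp)
    is_lnc = res.index.isin(lnc_genes)
    de_lnc = de.call_de(res[is_lnc], alpha=config.alpha, lfc=config.lfc)
    de_genes = de.call_de(res[~is_lnc], alpha=config.alpha, lfc=config.lfc)
    return de_genes, de_lnc


def normalized_log_expression(matrix: CountMatrix,
                              exclude: tuple[str, ...] = ()) -> pd.DataFrame:
    if exclude:
        matrix = matrix.drop_samples(list(exclude))
    X = matrix.counts.to_numpy(dtype=float)
    factors = de.size_factors(X)
    return pd.DataFrame(np.log2(X / factors[None, :] + 1.0),
                        index=matrix.feature_ids, columns=matrix.sample_ids)


def run_all(query_gtf: str | Path, query_fasta: str | Path,
            reference_gtf: str | Path, reference_fasta: str | Path,
            counts_tsv: str | Path, groups_tsv: str | Path,
            outdir: str | Path, config: PipelineConfig,
            hits_tsv: str | Path | None = None,
            subject_classes: dict[str, str] | None = None) -> RunResult:
    """Run every stage on files, writing per-stage outputs and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    queries = formats.read_gtf(query_gtf)
    query_seqs = {r.id: r.sequence for r in formats.read_fasta(query_fasta)}
    missing = [t.transcript_id for t in queries if t.transcript_id not in query_seqs]
    if missing:
        raise ValueError(f"query transcripts without sequence: {missing[:5]}")
    reference = formats.read_gtf(reference_gtf)
    ref_seqs = {r.id: r.sequence for r in formats.read_fasta(reference_fasta)}
    groups_df = pd.read_csv(groups_tsv, sep="\t")
    group_map = dict(zip(groups_df.iloc[:, 0], groups_df.iloc[:, 1]))
    matrix = formats.read_count_table(counts_tsv, group_map)
    hits = (formats.read_hit_table(hits_tsv, subject_classes or {})
            if hits_tsv else None)

    logger.info("stage filter+classify: %d queries vs %d reference transcripts",
                len(queries), len(reference))
    ident = identify_lncRNAs(queries, query_seqs, reference, ref_seqs,
                             config, hits=hits)

    formats.write_removal_log(ident["removal_log"], outdir / "removal_log.tsv")
    with open(outdir / "novel_lncRNAs.txt", "w", newline="\n") as fh:
        fh.writelines(t + "\n" for t in sorted(ident["novel_lncRNAs"]))
    with open(outdir / "annotated_lncRNAs.txt", "w", newline="\n") as fh:
        fh.writelines(t + "\n" for t in sorted(ident["annotated_lncRNAs"]))
    by_id = {t.transcript_id: t for t in queries}
    novel_models = [by_id[t] for t in sorted(ident["novel_lncRNAs"])]
    formats.write_gtf(novel_models, outdir / "novel_lncRNAs.gtf")
    formats.write_fasta([SequenceRecord(t, query_seqs[t])
                         for t in sorted(ident["novel_lncRNAs"])],
                        outdir / "novel_lncRNAs.fa")
    with open(outdir / "classifier_metadata.json", "w", newline="\n") as fh:
        json.dump(ident["model"].metadata, fh, indent=1, sort_keys=True)

    logger.info("stage de: %d features x %d samples",
                len(matrix.feature_ids), len(matrix.sample_ids))
    qc = de.sample_qc(matrix)
    qc.pca.round(6).to_csv(outdir / "qc_pca.tsv", sep="\t")
    qc.distances.round(6).to_csv(outdir / "qc_distances.tsv", sep="\t")
    with open(outdir / "qc_report.json", "w", newline="\n") as fh:
        json.dump({"outlier_flags": qc.outliers,
                   "explained_variance_ratio": [round(v, 6) for v in
                                                qc.explained_variance_ratio],
                   "excluded_samples": list(config.exclude_samples)},
                  fh, indent=1, sort_keys=True)

    gene_biotype: dict[str, str] = {}
    for t in reference:
        gene_biotype.setdefault(t.gene_id, t.biotype)
    lnc_genes = {g for g, b in gene_biotype.items() if b == "lncRNA"}
    de_genes, de_lnc = run_de_split(matrix, lnc_genes, config)
    de_genes.round(8).rename_axis("feature_id").to_csv(outdir / "de_genes.tsv", sep="\t")
    de_lnc.round(8).rename_axis("feature_id").to_csv(outdir / "de_lncRNAs.tsv", sep="\t")

    degs = list(de_genes.index[de_genes["call"] != "ns"])
    dels = list(de_lnc.index[de_lnc["call"] != "ns"])
    logger.info("stage targets: %d DELs x %d DEGs", len(dels), len(degs))
    expr = normalized_log_expression(matrix, config.exclude_samples)
    cis = targets.cis_candidates(dels, degs, reference, window=config.cis_window)
    edges = targets.build_target_network(
        expr.loc[[d for d in dels if d in expr.index]],
        expr.loc[[g for g in degs if g in expr.index]],
        cis, r_min=config.r_min, alpha=config.alpha)
    edge_df = targets.edges_to_frame(edges)
    edge_df.round(8).to_csv(outdir / "target_edges.tsv", sep="\t", index=False)

    lnc_models = [t for t in reference if t.biotype == "lncRNA"]
    mrna_models = [t for t in reference if t.biotype == "protein_coding"]
    summary = targets.structure_summary(lnc_models, mrna_models)
    summary.stats.round(4).to_csv(outdir / "structure_stats.tsv", sep="\t")
    with open(outdir / "structure_report.json", "w", newline="\n") as fh:
        json.dump({"pvalues": summary.pvalues,
                   "edge_metadata": targets.EDGE_METADATA},
                  fh, indent=1, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "checksums": {},
    }
    for p in sorted(outdir.iterdir()):
        if p.name not in ("manifest.json", "run.log") and p.is_file():
            manifest["checksums"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return RunResult(outdir, ident["cascade"], ident["novel_lncRNAs"],
                     ident["annotated_lncRNAs"], de_genes, de_lnc, edges,
                     manifest)
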