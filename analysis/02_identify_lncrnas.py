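#!/usr/bin/env python
"""Identify lncRNAs among the assembled transcripts.

Class codes against the reference, the retention cascade (codes x/o/i/u/j
kept, < 200 nt or single-exon removed, duplicates collapsed), the long-ORF
exclusion, the cross-validated coding-potential random forest, and homology
triage.  Scores the calls against the planted truth and writes tables under
results/identification/.
"""

from collections import Counter
from pathlib import Path

from lncpipe import formats
from lncpipe.pipeline import PipelineConfig, identify_lncRNAs, score_identification
from lncpipe.simulate import GroundTruth

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUTDIR = ROOT / "results" / "identification"
SEED = 1


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    queries = formats.read_gtf(STUDY / "assembled.gtf")
    query_seqs = {r.id: r.sequence
                  for r in formats.read_fasta(STUDY / "assembled_transcripts.fa")}
    reference = formats.read_gtf(STUDY / "reference.gtf")
    ref_seqs = {r.id: r.sequence
                for r in formats.read_fasta(STUDY / "reference_transcripts.fa")}
    truth = GroundTruth.from_json(STUDY / "ground_truth.json")

    res = identify_lncRNAs(queries, query_seqs, reference, ref_seqs,
                           PipelineConfig(seed=SEED))

    codes = Counter(c.code for c in res["class_codes"].values())
    print("class codes:", dict(sorted(codes.items())))
    meta = res["model"].metadata
    print(f"classifier: {meta['hyperparameters']}, "
          f"CV F1 {meta['cv_mean_f1']:.3f}, held-out F1 {meta['heldout_f1']:.3f}")
    print(f"novel lncRNAs: {len(res['novel_lncRNAs'])}, "
          f"annotated lncRNAs: {len(res['annotated_lncRNAs'])}")
    stages = Counter(stage for stage, _ in res["removal_log"].values())
    print("removals by stage:", dict(sorted(stages.items())))
    score = score_identification(res["novel_lncRNAs"], truth)
    print(f"vs truth: sensitivity {score['sensitivity']:.3f}, "
          f"contamination {score['contamination']:.3f}")

    formats.write_removal_log(res["removal_log"], OUTDIR / "removal_log.tsv")
    for name, ids in (("novel_lncRNAs.txt", res["novel_lncRNAs"]),
                      ("annotated_lncRNAs.txt", res["annotated_lncRNAs"])):
        with open(OUTDIR / name, "w", newline="\n") as fh:
            fh.writelines(t + "\n" for t in sorted(ids))


if __name__ == "__main__":
    main()
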