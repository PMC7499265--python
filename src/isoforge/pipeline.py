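"""End-to-end orchestration: simulate (optional) -> FLNC -> collapse/stats ->
refine -> AS events -> Ks/WGD -> expression, with a consolidated JSON report.

All outputs are plain TSV/JSON. The report is deterministic for a fixed
config; the artifact manifest (with checksums and a timestamp) is written
separately so reruns are byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import expression as xpr
from . import flnc, kswgd, refine, splicing
from .models import collapse_by_intron_chain, compute_stats, parse_models, write_bed12
from .simulate import SimulationConfig, TruthSet, generate_dataset

log = logging.getLogger("isoforge")


@dataclass
class PipelineConfig:
    outdir: Path
    simulation: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)  # paths when not simulating
    flnc_params: dict = field(default_factory=dict)
    collapse_params: dict = field(default_factory=dict)
    refine_params: dict = field(default_factory=dict)
    kswgd_params: dict = field(default_factory=dict)
    expression_params: dict = field(default_factory=dict)
    resume: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = d.get("simulation")
        return cls(
            outdir=Path(d["outdir"]),
            simulation=SimulationConfig(**sim) if sim is not None else None,
            inputs=d.get("inputs", {}),
            flnc_params=d.get("flnc", {}),
            collapse_params=d.get("collapse", {}),
            refine_params=d.get("refine", {}),
            kswgd_params=d.get("kswgd", {}),
            expression_params=d.get("expression", {}),
            resume=bool(d.get("resume", False)),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.simulation is None:
            required = {"reads", "annotation", "alignments", "isoforms",
                        "homology", "counts", "grouping", "paralogs_dir",
                        "primer5", "primer3"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing: {sorted(missing)}")
            for key in required - {"primer5", "primer3"}:
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input {key}={self.inputs[key]} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _precision_recall(predicted: set, truth: set) -> dict:
    tp = len(predicted & truth)
    return {
        "precision": tp / len(predicted) if predicted else float("nan"),
        "recall": tp / len(truth) if truth else float("nan"),
        "n_predicted": len(predicted),
        "n_truth": len(truth),
    }


def group_loci(models) -> list[list]:
    """Group transcript models into loci: connected components of span overlap
    on the same chromosome and strand."""
    out = []
    by_cs: dict[tuple, list] = {}
    for m in models:
        by_cs.setdefault((m.chrom, m.strand), []).append(m)
    for key in sorted(by_cs):
        ms = sorted(by_cs[key], key=lambda m: (m.start, m.transcript_id))
        cur: list = []
        cur_end = -1
        for m in ms:
            if cur and m.start < cur_end:
                cur.append(m)
                cur_end = max(cur_end, m.end)
            else:
                if cur:
                    out.append(cur)
                cur = [m]
                cur_end = m.end
        if cur:
            out.append(cur)
    return out


def _stage(name: str, t0: float, **params) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
             " ".join(f"{k}={v}" for k, v in params.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = config.outdir
    report_path = outdir / "report.json"
    if outdir.exists() and any(outdir.iterdir()) and not config.resume:
        raise FileExistsError(
            f"{outdir} is not empty; pass resume=True to overwrite a partial run"
        )
    results = outdir / "results"
    results.mkdir(parents=True, exist_ok=True)

    truth: TruthSet | None = None
    if config.simulation is not None:
        t0 = time.perf_counter()
        data = outdir / "data"
        truth = generate_dataset(config.simulation, data)
        sim = config.simulation
        inputs = {
            "reads": data / "reads.fasta",
            "annotation": data / "annotation.gff3",
            "alignments": data / "alignments.bed",
            "isoforms": data / "isoforms.fasta",
            "homology": data / "homology.tsv",
            "counts": data / "counts.tsv",
            "grouping": data / "grouping.tsv",
            "paralogs_dir": data / "paralogs",
            "primer5": sim.primer5,
            "primer3": sim.primer3,
        }
        _stage("simulate", t0, seed=sim.seed, n_genes=sim.n_genes)
    else:
        inputs = {k: (v if k in ("primer5", "primer3") else Path(v))
                  for k, v in config.inputs.items()}
        if (Path(inputs["reads"]).parent / "truth.json").exists():
            truth = TruthSet.load(Path(inputs["reads"]).parent / "truth.json")

    report: dict = {"stages": {}}

    # ---- FLNC classification -------------------------------------------
    t0 = time.perf_counter()
    params = flnc.FlncParams(**config.flnc_params)
    records = flnc.classify_file(inputs["reads"], inputs["primer5"], inputs["primer3"], params)
    summary = flnc.summarize_library(records, "all_libraries")
    flnc.write_records(records, results / "flnc_records.tsv")
    flnc.write_summaries([summary, flnc.aggregate_summaries([summary])],
                         results / "flnc_summary.tsv")
    report["stages"]["flnc"] = {
        f: getattr(summary, f) for f in flnc.LibrarySummary.FIELDS
    }
    _stage("flnc", t0, n_reads=len(records))

    # ---- collapse and completeness stats --------------------------------
    t0 = time.perf_counter()
    alignments = parse_models(inputs["alignments"], "BED12")
    collapsed = collapse_by_intron_chain(alignments, **config.collapse_params)
    write_bed12(collapsed, results / "collapsed.bed")
    counts_df = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
    lengths = {
        rec.id: len(rec.seq) for rec in SeqIO.parse(str(inputs["isoforms"]), "fasta")
    }
    mat = xpr.ExpressionMatrix.from_counts(counts_df, lengths)
    mean_tpm = mat.tpm.mean(axis=1)
    expr_vec = [float(mean_tpm.get(m.transcript_id, 0.0)) for m in collapsed]
    stats = compute_stats(collapsed, expr_vec)
    report["stages"]["assembly_stats"] = dataclasses.asdict(stats)
    _stage("collapse", t0, n_in=len(alignments), n_out=len(collapsed))

    # ---- annotation refinement ------------------------------------------
    t0 = time.perf_counter()
    annotation = parse_models(inputs["annotation"], "GFF3")
    rp = dict(config.refine_params)
    orf_min = rp.pop("orf_min_codons", 100)
    proposals = refine.detect_split_genes(alignments, annotation, **rp)
    refine.write_merge_proposals(proposals, results / "merge_proposals.tsv")

    isoform_ids = set(lengths)
    aligned_ids = {m.transcript_id for m in alignments}
    unaligned = isoform_ids - aligned_ids
    calls, novel_totals = refine.classify_novel_isoforms(alignments, unaligned, annotation)
    refine.write_novel_calls(calls, results / "novel_calls.tsv")

    novel_ids = {c.transcript_id for c in calls}
    novel_models = [m for m in alignments if m.transcript_id in novel_ids]
    profile = (
        refine.intron_count_profile(novel_models, alignments) if novel_models else None
    )

    seqs = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(inputs["isoforms"]), "fasta")
        if rec.id in novel_ids
    }
    hom = pd.read_csv(inputs["homology"], sep="\t", index_col=0)["hit"].to_dict()
    lnc_calls, venn = refine.call_lncrna(
        seqs, {k: bool(v) for k, v in hom.items() if k in seqs}, orf_min
    )
    refine.write_lncrna_calls(lnc_calls, results / "lncrna_calls.tsv")
    report["stages"]["refine"] = {
        "split": refine.split_gene_counts(proposals),
        "novel_totals": novel_totals,
        "novel_grand_total": refine.novel_grand_total(novel_totals),
        "venn": venn,
        "lncrna_total": refine.lncrna_total(venn),
        "intron_profile_novel": {str(k): v for k, v in (profile[0] if profile else {}).items()},
    }
    _stage("refine", t0, n_proposals=len(proposals), n_novel=len(calls))

    # ---- AS events --------------------------------------------------------
    t0 = time.perf_counter()
    events = []
    for locus in group_loci(alignments):
        events.extend(splicing.enumerate_events(locus))
    as_summary = splicing.summarize_events(events)
    splicing.write_events(events, results / "as_events.tsv")
    splicing.write_summary(as_summary, results / "as_summary.tsv")
    report["stages"]["as_events"] = {
        "counts": as_summary.counts,
        "total": as_summary.total,
        "percents": as_summary.percents,
    }
    _stage("asevents", t0, n_events=len(events))

    # ---- Ks / WGD ---------------------------------------------------------
    t0 = time.perf_counter()
    kw = dict(config.kswgd_params)
    rate = kw.pop("substitution_rate", 6.5e-9)
    pair_files = sorted(Path(inputs["paralogs_dir"]).glob("*.fasta"))
    estimates = [kswgd.ng86_from_fasta(p) for p in pair_files]
    kswgd.write_estimates(estimates, results / "ks_estimates.tsv")
    ks_block: dict = {"n_pairs": len(estimates)}
    try:
        peak = kswgd.ks_distribution_peak(estimates, **kw)
        ks_block.update(
            mode_ks=peak.mode_ks,
            n_pairs_used=peak.n_pairs_used,
            wgd_time_mya=round(kswgd.ks_to_time(peak.mode_ks, rate) / 1e6, 2),
            substitution_rate=rate,
        )
    except ValueError as exc:
        ks_block["peak_error"] = str(exc)
    report["stages"]["ks_wgd"] = ks_block
    _stage("kswgd", t0, n_pairs=len(estimates))

    # ---- expression --------------------------------------------------------
    t0 = time.perf_counter()
    grouping = pd.read_csv(inputs["grouping"], sep="\t")
    pcc = xpr.replicate_pcc(mat.tpm)
    pcc.to_csv(results / "pcc_matrix.tsv", sep="\t")
    mat.tpm.round(4).to_csv(results / "tpm.tsv", sep="\t")
    mat.fpkm.round(4).to_csv(results / "fpkm.tsv", sep="\t")
    gene_to_isoforms: dict[str, list[str]] = {}
    for tid in sorted(isoform_ids):
        gene = tid.rsplit("_t", 1)[0] if "_t" in tid else tid
        gene_to_isoforms.setdefault(gene, []).append(tid)
    rep = xpr.representative_isoform(
        gene_to_isoforms, pd.Series(lengths), mean_tpm, **config.expression_params
    )
    pd.Series(rep, name="representative").rename_axis("gene").to_csv(
        results / "representative_isoforms.tsv", sep="\t"
    )
    profile_df = xpr.tissue_profile(mat.tpm, grouping)
    profile_df.round(4).to_csv(results / "tissue_profile.tsv", sep="\t")
    min_r = float(pcc.to_numpy().min())
    report["stages"]["expression"] = {
        "n_transcripts": int(mat.counts.shape[0]),
        "n_samples": int(mat.counts.shape[1]),
        "min_pcc": min_r,
        "tpm_sums_ok": bool(abs(mat.tpm.sum() - 1e6).max() < 1e-3),
    }
    _stage("expression", t0, n_samples=mat.counts.shape[1])

    # ---- recovery vs planted truth -----------------------------------------
    if truth is not None:
        label_map = {"chimeric": "full_length_chimeric"}
        n_ok = sum(
            r.klass == label_map.get(truth.read_labels[r.read_id], truth.read_labels[r.read_id])
            for r in records
            if r.read_id in truth.read_labels
        )
        pred_components = {p.component_genes for p in proposals}
        truth_components = {frozenset(c) for c in truth.split_components}
        pred_novel = {(c.transcript_id, c.category) for c in calls}
        truth_novel = set(truth.novel_categories.items())
        pred_nc = {c.transcript_id for c in lnc_calls if c.channel_coding_potential == "noncoding"}
        pred_events = {e.key for e in events}
        truth_events = {e.key for e in truth.planted_events}
        report["recovery"] = {
            "flnc_accuracy": n_ok / len(records) if records else float("nan"),
            "split_genes": _precision_recall(pred_components, truth_components),
            "novel_isoforms": _precision_recall(pred_novel, truth_novel),
            "noncoding": _precision_recall(pred_nc, set(truth.noncoding_ids)),
            "as_events": _precision_recall(pred_events, truth_events),
        }

    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
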