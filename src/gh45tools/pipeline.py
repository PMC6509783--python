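"""End-to-end workflow: cluster -> trim -> diagnose -> introns -> treescan.

``run_all`` composes the stages into the family-screening workflow and
writes a consolidated report: a JSON document plus a human-readable
summary, with each stage's table saved alongside.  Every threshold is
echoed into the report for provenance, and all counts in the report are
re-derivable from the stage TSVs.  The report body is deterministic for
identical inputs (timestamps appear only in the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import genestruct, redundancy, resdiag, seqmodel, treescan

log = logging.getLogger("gh45tools")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage name."""


@dataclass
class RunConfig:
    """Inputs, thresholds and group definitions for one pipeline run."""

    fasta: str
    outdir: str
    msa: str | None = None
    gff3: str | None = None
    tree: str | None = None
    lineage_tsv: str | None = None
    scheme: str | None = None                 # None -> bundled GH45 scheme
    identity_threshold: float = 0.90
    max_gap_fraction: float = 0.5
    intron_tolerance: int = 0
    group_label: str = "group"
    group_level: int = 0                      # lineage level defining the group
    group_value: str | None = None
    outgroup_level: int = 0
    outgroup_value: str | None = None
    sister_level: int = 0                     # lineage level for the histogram
    verbosity: int = 1

    def validate(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError("max_gap_fraction must be in [0, 1]")
        if self.intron_tolerance < 0:
            raise ValueError("intron_tolerance must be >= 0")
        for name in ("fasta", "msa", "gff3", "tree", "lineage_tsv", "scheme"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} input not found: {path}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("cluster")
def _run_cluster(seqs, cfg, outdir):
    cs = redundancy.greedy_cluster(seqs, cfg.identity_threshold)
    redundancy.write_cluster_tsv(cs, outdir / "clusters.tsv")
    redundancy.write_representatives(cs, outdir / "representatives.faa")
    log.info("cluster: %d sequences -> %d clusters at %.2f identity",
             len(seqs), cs.n_clusters, cfg.identity_threshold)
    return cs


@_stage("trim")
def _run_trim(cfg, outdir):
    aln = seqmodel.read_alignment(cfg.msa, taxonomy_tsv=cfg.lineage_tsv)
    trimmed = seqmodel.trim_columns(aln, cfg.max_gap_fraction)
    seqmodel.write_fasta(trimmed.rows, outdir / "trimmed.afa")
    log.info("trim: %d -> %d columns (max gap fraction %.2f)",
             aln.ncol, trimmed.ncol, cfg.max_gap_fraction)
    return aln, trimmed


@_stage("diagnose")
def _run_diagnose(seqs, cfg, msa, outdir):
    scheme = (resdiag.load_scheme(cfg.scheme) if cfg.scheme
              else resdiag.default_scheme())
    use_msa = None
    if msa is not None and scheme.reference.id in msa.ids():
        use_msa = msa
    queries = [s for s in seqs if s.id != scheme.reference.id]
    profiles = resdiag.diagnose(queries, scheme, msa=use_msa)
    frame = resdiag.profiles_to_frame(profiles, scheme)
    frame.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
    log.info("diagnose: %d queries (%s mode)", len(profiles),
             "msa" if use_msa is not None else "pairwise")
    return profiles, frame


@_stage("introns")
def _run_introns(cfg, msa, outdir):
    models = genestruct.read_gene_models(cfg.gff3)
    by_id = {m.gene_id: m for m in models}
    introns = [rec for m in models for rec in genestruct.compute_introns(m)]
    projected = genestruct.project_introns(introns, msa, gene_models=by_id)
    groups = genestruct.conserved_intron_groups(projected,
                                               cfg.intron_tolerance)
    genestruct.write_intron_tsv(projected, outdir / "introns.tsv")
    log.info("introns: %d genes, %d introns, %d conserved groups "
             "(tolerance %d)", len(models), len(projected), len(groups),
             cfg.intron_tolerance)
    return models, projected, groups


@_stage("treescan")
def _run_treescan(cfg, outdir):
    tree = treescan.read_newick(cfg.tree)
    taxonomy = seqmodel.read_taxonomy_tsv(cfg.lineage_tsv)

    def level(lin, k):
        return lin[k] if k < len(lin) else None

    group = {rid for rid, (_, lin) in taxonomy.items()
             if level(lin, cfg.group_level) == cfg.group_value}
    outgroup = None
    if cfg.outgroup_value is not None:
        outgroup = {rid for rid, (_, lin) in taxonomy.items()
                    if level(lin, cfg.outgroup_level) == cfg.outgroup_value}
    lineage_map = {rid: level(lin, cfg.sister_level) or "unknown"
                   for rid, (_, lin) in taxonomy.items()}
    report = treescan.clade_report(tree, cfg.group_label, group,
                                   lineage=lineage_map, outgroup=outgroup)
    (outdir / "clade_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    log.info("treescan: group %r (%d leaves) monophyletic=%s origins=%s",
             cfg.group_label, len(group), report.is_monophyletic,
             report.n_origins)
    return report


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage whose inputs are configured; return the report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.DEBUG if cfg.verbosity > 1 else logging.INFO)
    try:
        report: dict = {"parameters": asdict(cfg), "counts": {}}

        seqs = seqmodel.read_fasta(cfg.fasta, taxonomy_tsv=cfg.lineage_tsv)
        report["counts"]["sequences_in"] = len(seqs)

        cs = _run_cluster(seqs, cfg, outdir)
        report["counts"]["clusters"] = cs.n_clusters
        report["clusters"] = [
            {"representative": c.representative.id, "size": c.size,
             "members": c.ids()} for c in cs.clusters
        ]

        msa = trimmed = None
        if cfg.msa is not None:
            msa, trimmed = _run_trim(cfg, outdir)
            report["counts"]["msa_columns_in"] = msa.ncol
            report["counts"]["msa_columns_kept"] = trimmed.ncol

        profiles, frame = _run_diagnose(seqs, cfg, msa, outdir)
        report["function_classification"] = frame.to_dict(orient="records")
        report["counts"]["label_tally"] = (
            frame["label"].value_counts().sort_index().to_dict()
        )

        if cfg.gff3 is not None:
            if msa is None:
                raise PipelineError(
                    "stage 'introns' failed: an MSA is required to project "
                    "introns"
                )
            models, projected, groups = _run_introns(cfg, msa, outdir)
            report["counts"]["genes"] = len(models)
            report["counts"]["introns"] = len(projected)
            report["counts"]["intron_groups"] = len(groups)
            report["intron_groups"] = [
                {"phase": g.phase, "columns": g.columns,
                 "n_genes": g.n_genes, "genes": sorted(g.gene_ids),
                 "in_signal_peptide": g.in_signal_peptide}
                for g in groups
            ]

        if cfg.tree is not None:
            if cfg.lineage_tsv is None or cfg.group_value is None:
                raise PipelineError(
                    "stage 'treescan' failed: lineage_tsv and group_value "
                    "are required"
                )
            clade = _run_treescan(cfg, outdir)
            report["clade_report"] = clade.to_dict()

        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (outdir / "summary.txt").write_text(_summarise(report))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _summarise(report: dict) -> str:
    c = report["counts"]
    lines = ["gh45tools consolidated report", "=" * 30, ""]
    p = report["parameters"]
    lines.append(f"identity threshold : {p['identity_threshold']}")
    lines.append(f"max gap fraction   : {p['max_gap_fraction']}")
    lines.append(f"intron tolerance   : {p['intron_tolerance']}")
    lines.append("")
    lines.append(f"sequences in       : {c['sequences_in']}")
    lines.append(f"clusters           : {c['clusters']}")
    if "msa_columns_in" in c:
        lines.append(f"alignment columns  : {c['msa_columns_in']} -> "
                     f"{c['msa_columns_kept']}")
    if "label_tally" in c:
        tally = ", ".join(f"{k}={v}" for k, v in c["label_tally"].items())
        lines.append(f"function labels    : {tally}")
    if "intron_groups" in c:
        lines.append(f"introns / groups   : {c['introns']} / "
                     f"{c['intron_groups']}")
    if "clade_report" in report:
        cr = report["clade_report"]
        lines.append("")
        lines.append(f"clade {cr['group']!r}: monophyletic="
                     f"{cr['is_monophyletic']} support={cr['support']} "
                     f"origins={cr['n_origins']}")
        if cr["sister_composition"]:
            comp = ", ".join(f"{k}={v}" for k, v in
                             sorted(cr["sister_composition"].items()))
            lines.append(f"sister composition : {comp}")
    return "\n".join(lines) + "\n"
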