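"""End-to-end pipeline: QC -> LD/block size -> frequencies -> tree fit ->
migration edges -> bootstrap support -> f-statistics, from one YAML config.

Every stage writes its outputs plus a ``manifest.json`` entry recording
inputs, parameters and outputs; a completed stage whose outputs still exist
is skipped on rerun, so deleting a late-stage output recomputes only the
downstream stages.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import edge_support, fstats, genotype_io, graphfit, ld_blocks, qc_filters
from .tree_utils import select_best_trees, strict_consensus

logger = logging.getLogger(__name__)

DEFAULTS = {
    "sample_missingness": 0.2,
    "snp_missingness": 0.2,
    "maf": 0.01,
    "ld_window_kb": 500,
    "ld_bin": 75,
    "blocksize_threshold_kb": 200,
    "block_size": None,  # None = determine from the SNP map
    "n_migrations": 8,
    "n_searches": 10,
    "n_bootstrap": 100,
    "seed": 0,
}

STAGES = ["qc", "blocksize", "freqs", "fit", "migrations", "bootstrap", "fstats"]


def _load_config(config):
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(DEFAULTS)
    cfg.update(config)
    for key in ("genotypes", "pop_map", "outgroup", "outdir"):
        if key not in cfg:
            raise KeyError(f"config missing required key {key!r}")
    return cfg


def run_pipeline(config) -> Path:
    """Run the full workflow; returns the run directory.

    ``config`` is a mapping or YAML path with keys: ``genotypes`` (TSV path),
    ``pop_map`` (TSV sample->population), ``outgroup``, ``outdir``, optional
    ``exclude`` (file of sample ids), ``fstat_tests`` (list of
    [stat, pops...]), and the threshold/size defaults above.
    """
    cfg = _load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    state: dict = {}

    def done(stage, outputs):
        rec = manifest.get(stage)
        return rec is not None and all(Path(p).exists() for p in rec["outputs"])

    def record(stage, params, outputs):
        manifest[stage] = {"params": params, "outputs": [str(p) for p in outputs]}
        # invalidate downstream stages
        for later in STAGES[STAGES.index(stage) + 1:]:
            manifest.pop(later, None)
        manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        _run_stages(cfg, outdir, manifest, state, done, record)
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e
    return outdir


def _run_stages(cfg, outdir, manifest, state, done, record):
    seed = int(cfg["seed"])

    # -- qc -----------------------------------------------------------------
    qc_out = outdir / "qc.genotypes.tsv"
    if not done("qc", None):
        G = genotype_io.read_genotype_table(cfg["genotypes"], cfg.get(
            "genotype_format", "tsv"))
        exclude = []
        if cfg.get("exclude"):
            exclude = Path(cfg["exclude"]).read_text().split()
        G, report = qc_filters.qc_pipeline(
            G, exclude, cfg["sample_missingness"], cfg["snp_missingness"],
            cfg["maf"])
        genotype_io.write_genotype_table(G, qc_out)
        (outdir / "qc.removed.tsv").write_text(
            "\n".join(["type\tid"]
                      + [f"sample\t{s}" for s in report.removed_samples]
                      + [f"snp\t{s}" for s in report.removed_snps]) + "\n")
        record("qc", {k: cfg[k] for k in
                      ("sample_missingness", "snp_missingness", "maf")},
               [qc_out, outdir / "qc.removed.tsv"])
    G = genotype_io.read_genotype_table(qc_out, "tsv")
    state["G"] = G

    # -- block size ---------------------------------------------------------
    bs_out = outdir / "blocksize.json"
    if not done("blocksize", None):
        if cfg["block_size"]:
            k, trace = int(cfg["block_size"]), None
        else:
            k, trace = ld_blocks.determine_block_size(
                G.snps, cfg["blocksize_threshold_kb"])
        bs_out.write_text(json.dumps({"k": k}))
        if trace is not None:
            trace.to_csv(outdir / "blocksize.trace.tsv", sep="\t", index=False)
        record("blocksize", {"threshold_kb": cfg["blocksize_threshold_kb"]},
               [bs_out])
    k = json.loads(bs_out.read_text())["k"]

    # -- frequencies --------------------------------------------------------
    freq_out = outdir / "freqs.treemix.gz"
    pop_map = _read_pop_map(cfg["pop_map"])
    if not done("freqs", None):
        table = genotype_io.stratified_allele_freqs(
            genotype_io.minor_allele_recode(G), pop_map)
        genotype_io.write_treemix_freqs(table, freq_out)
        G.snps.to_csv(outdir / "freqs.snps.tsv", sep="\t", index=False)
        record("freqs", {}, [freq_out])
    import pandas as pd
    snps = pd.read_csv(outdir / "freqs.snps.tsv", sep="\t")
    table = genotype_io.read_treemix_freqs(freq_out, snps=snps)

    # -- tree fit -----------------------------------------------------------
    fit_out = outdir / "tree.nwk"
    cov = graphfit.covariance_matrix(table, block=k)
    if not done("fit", None):
        fits = graphfit.fit_tree(cov, cfg["outgroup"],
                                 n_searches=int(cfg["n_searches"]), seed=seed)
        best, n_best = select_best_trees(fits)
        consensus = strict_consensus([g for g, _ in best]) \
            if len(best) > 1 else best[0][0]
        fit_out.write_text(best[0][0].newick() + "\n")
        (outdir / "tree.consensus.nwk").write_text(
            consensus.newick(lengths=False) + "\n")
        rep = graphfit.tree_fit_report(best[0][0], cov)
        (outdir / "tree.summary.json").write_text(json.dumps({
            "loglik": rep.loglik, "variance_explained": rep.variance_explained,
            "n_best": n_best, "n_distinct_topologies": len(best),
        }, indent=2))
        state["tree"] = best[0][0]
        record("fit", {"n_searches": cfg["n_searches"], "k": k}, [fit_out])
    else:
        state["tree"] = _reload_tree(fit_out, cov, cfg["outgroup"])

    # -- migrations ---------------------------------------------------------
    mig_out = outdir / "migrations.tsv"
    m = int(cfg["n_migrations"])
    if not done("migrations", None):
        report = graphfit.add_migration_edges(state["tree"], cov, m, seed=seed)
        _write_migrations(report, mig_out)
        (outdir / "migrations.summary.json").write_text(json.dumps({
            "loglik": report.loglik,
            "variance_explained": report.variance_explained,
        }, indent=2))
        state["report"] = report
        record("migrations", {"m": m}, [mig_out])
    else:
        report = graphfit.add_migration_edges(state["tree"], cov, m, seed=seed,
                                              compute_pvalues=False)
        state["report"] = report

    # -- bootstrap ----------------------------------------------------------
    boot_out = outdir / "bootstrap.support.tsv"
    if not done("bootstrap", None):
        reps = []
        for b in range(int(cfg["n_bootstrap"])):
            rt = edge_support.bootstrap_block_resample(table, k, seed + 1000 + b)
            rcov = graphfit.covariance_matrix(rt, block=k)
            rfit = graphfit.fit_tree(rcov, cfg["outgroup"], n_searches=1,
                                     seed=seed + b)[0][0]
            reps.append(graphfit.add_migration_edges(
                rfit, rcov, m, seed=seed + b, compute_pvalues=False))
        summaries = edge_support.summarize_migrations([state["report"]], reps)
        _write_summaries(summaries, boot_out)
        record("bootstrap", {"reps": cfg["n_bootstrap"]}, [boot_out])

    # -- f-statistics -------------------------------------------------------
    fstat_out = outdir / "fstats.tsv"
    if not done("fstats", None):
        rows = []
        for test in cfg.get("fstat_tests", []):
            stat, *pops = test
            if stat == "f3":
                r = fstats.f3_admixture(table, *pops, block=k)
            elif stat == "f3o":
                r = fstats.f3_outgroup(table, *pops, block=k)
            elif stat == "f4":
                r = fstats.f4(table, *pops, block=k)
            else:
                raise ValueError(f"unknown test type {stat!r}")
            rows.append((r.name, ";".join(r.pops), r.estimate, r.se, r.z, r.p))
        lines = ["test\tpops\testimate\tse\tz\tp\tholm_reject"]
        if rows:
            reject, _ = fstats.holm_bonferroni([r[5] for r in rows])
            for r, rej in zip(rows, reject):
                lines.append("\t".join(map(str, r)) + f"\t{int(rej)}")
        fstat_out.write_text("\n".join(lines) + "\n")
        record("fstats", {"n_tests": len(cfg.get("fstat_tests", []))},
               [fstat_out])


def _read_pop_map(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sid, pop = line.split()[:2]
        out[sid] = pop
    return out


def _reload_tree(path, cov, outgroup):
    from .graphfit import fit_branch_lengths
    from .tree_utils import read_newick

    graph = read_newick(str(path))
    graph.outgroup = outgroup
    graph, _ = fit_branch_lengths(graph, cov)
    return graph


def _write_migrations(report, path):
    lines = ["origin\tdestination\tweight\tjackknife_weight\tse\tp"]
    for info in report.migrations:
        lines.append("\t".join([
            ",".join(sorted(info.origin_tips)),
            ",".join(sorted(info.dest_tips)),
            f"{info.weight:.4f}",
            "" if info.jackknife_weight is None else f"{info.jackknife_weight:.4f}",
            "" if info.se is None else f"{info.se:.4f}",
            "" if info.p is None else f"{info.p:.3e}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_summaries(summaries, path):
    lines = ["edge\torigin\tdestination\tN\tw_mean\tw_jackknife\tse\tp\tMS\tMS_E"]
    for s in summaries:
        lines.append("\t".join([
            s.label, ",".join(sorted(s.origin_tips)),
            ",".join(sorted(s.dest_tips)), str(s.n_runs),
            f"{s.mean_weight:.4f}",
            "" if s.jackknife_weight is None else f"{s.jackknife_weight:.4f}",
            "" if s.se is None else f"{s.se:.4f}",
            "" if s.p is None else f"{s.p:.3e}",
            "" if s.ms is None else str(s.ms),
            "" if s.ms_e is None else str(s.ms_e),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
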