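"""End-to-end orchestration: cohort -> atlas -> models -> ordination ->
clusters -> motifs -> gene sets, with a manifest and run log."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import PeakAtlas, build_consensus, count_insertions, read_peak_beds
from .clustering import choose_k_gap, fold_change_groups, zscore_rows
from .config import PipelineConfig
from .differential import (
    ContrastSpec, aging_contrast, differentiation_contrast, fit_differential,
    filter_low_counts, normalize_and_weight, subset_age_contrast,
)
from .genes import geneset_shift_test, ease_enrichment, nearest_gene, read_gene_model, read_gmt
from .motifs import best_per_family, motif_enrichment, motif_intensity, read_motif_annotation
from .ordination import (
    ordering_probability, paired_stratified_perm_test, pc_loading_peaks,
    pca_scores, stratified_trend_test, top_variable_features,
    twosample_stratified_perm_test,
)
from .simulate import generate_cohort, write_fixture

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    output_dir: Path
    manifest: dict[str, int] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)

    def note(self, name: str, rows: int) -> None:
        self.manifest[name] = rows

    def log(self, msg: str) -> None:
        self.log_lines.append(msg)
        logger.info(msg)

    def write(self) -> None:
        with open(self.output_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        with open(self.output_dir / "run_log.txt", "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")


def _write(df: pd.DataFrame, out: Path, name: str, report: ReportBundle,
           index: bool = False) -> None:
    df.to_csv(out / name, sep="\t", index=index)
    report.note(name, len(df))


def _default_contrasts(lineages, subsets) -> list[ContrastSpec]:
    specs: list[ContrastSpec] = []
    for lin in lineages:
        specs.append(aging_contrast(lin, subsets))
        specs.append(differentiation_contrast(lin, subsets[-1], subsets[0]))
        for sub in subsets:
            specs.append(subset_age_contrast(lin, sub))
    return specs


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute every stage; writes TSVs + manifest + log under output_dir."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ReportBundle(out)
    report.log(f"tcellatac {__version__}; root seed {cfg.seed}")
    report.log("deviation: GC-content (CQN) normalization replaced by log-CPM")
    report.log("deviation: motif occurrences come from annotation tables, not PWM scanning")
    th = cfg.thresholds
    stage = "setup"
    try:
        # ---------------- cohort / inputs ----------------
        stage = "synthetic_cohort" if cfg.simulate is not None else "inputs"
        if cfg.simulate is not None:
            bundle = generate_cohort(cfg.simulate)
            fx = out / "fixture"
            write_fixture(bundle, fx)
            report.note("fixture", len(bundle.samples))
            samples = bundle.samples
            peak_calls = bundle.peak_calls
            insertions = bundle.insertions
            counts0 = bundle.atac_counts
            rna0 = bundle.rna_counts
            genes = bundle.genes
            motifs_ann = bundle.motifs
            gene_sets = bundle.gene_sets
            subsets = list(cfg.simulate.subsets)
            lineages = list(cfg.simulate.lineages)
        else:
            ip = cfg.inputs
            samples = pd.read_csv(ip.sample_sheet)
            subsets = list(dict.fromkeys(samples["subset"]))
            lineages = sorted(samples["lineage"].unique())
            samples["subset_rank"] = samples["subset"].map(
                {s: i for i, s in enumerate(subsets)})
            samples["group"] = samples["lineage"] + "_" + samples["subset"] + \
                "_" + samples["age_group"]
            samples = samples.set_index("sample", drop=False)
            sids = samples["sample"].tolist()
            peak_calls = None
            if ip.peaks_dir is not None:
                stage = "peak_atlas"
                peak_calls = read_peak_beds(
                    [Path(ip.peaks_dir) / f"{s}.bed" for s in sids], sids)
                stage = "inputs"
            insertions = None
            if ip.insertions_dir is not None:
                insertions = {}
                for s in sids:
                    df = pd.read_csv(Path(ip.insertions_dir) / f"{s}.bed", sep="\t",
                                     header=None, names=["chrom", "start", "end"])
                    insertions[s] = df.rename(columns={"start": "pos"})[["chrom", "pos"]]
            counts0 = (pd.read_csv(ip.atac_counts, sep="\t", index_col=0)
                       if ip.atac_counts else None)
            rna0 = (pd.read_csv(ip.rna_counts, sep="\t", index_col=0)
                    if ip.rna_counts else None)
            genes = read_gene_model(ip.genes) if ip.genes else None
            motifs_ann = read_motif_annotation(ip.motifs) if ip.motifs else None
            gene_sets = read_gmt(ip.gene_sets) if ip.gene_sets else None

        # ---------------- peak atlas ----------------
        stage = "peak_atlas"
        atlas = None
        if peak_calls is not None:
            atlas = build_consensus(peak_calls, th.min_consensus_samples, th.merge_frac)
            atlas.to_bed(out / "atlas.bed")
            report.note("atlas.bed", len(atlas))
            report.log(f"consensus atlas: {len(atlas)} peaks from {len(peak_calls)} samples")
        if insertions is not None and atlas is not None:
            chrom = getattr(cfg.simulate, "chrom", None)
            counts = count_insertions(insertions, atlas, chrom=chrom)
        else:
            if counts0 is None:
                raise ValueError("no insertions and no count matrix supplied")
            counts = counts0
            report.log("using supplied/planted count matrix (no insertion counting)")
        _write(counts.rename_axis("peak_id"), out, "atac_counts.tsv", report, index=True)

        # ---------------- differential (ATAC) ----------------
        stage = "differential_engine"
        counts = filter_low_counts(counts, th.min_cpm, th.min_cpm_samples)
        wm = normalize_and_weight(counts, samples["group"], samples["donor"])
        report.log(f"ATAC: {counts.shape[0]} peaks after filtering; rho={wm.rho:.3f}")
        contrasts = _default_contrasts(lineages, subsets)
        diff = fit_differential(wm, contrasts, robust=True)
        for spec in contrasts:
            tab = diff.for_contrast(spec.name).reset_index()
            _write(tab, out, f"differential_{spec.name}.tsv", report)
        report.log(f"moderation: prior df {diff.prior_df:.2f}, prior var {diff.prior_var:.4f}")

        rna_diff = None
        if rna0 is not None:
            rna_f = filter_low_counts(rna0, th.min_cpm, th.min_cpm_samples)
            rna_wm = normalize_and_weight(rna_f, samples["group"], samples["donor"])
            rna_specs = [subset_age_contrast(lin, subsets[0]) for lin in lineages]
            rna_diff = fit_differential(rna_wm, rna_specs, robust=True)
            for spec in rna_specs:
                _write(rna_diff.for_contrast(spec.name).reset_index(), out,
                       f"rna_differential_{spec.name}.tsv", report)

        # ---------------- ordination + permutation tests ----------------
        stage = "ordination_tests"
        top = top_variable_features(wm.logcpm, th.n_top_atac)
        pca = pca_scores(wm.logcpm.loc[top], n_components=3)
        _write(pca.scores.rename_axis("sample"), out, "pca_scores.tsv", report, index=True)
        _write(pca.loadings.rename_axis("feature_id"), out, "pca_loadings.tsv",
               report, index=True)
        _write(pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pca.variance_fractions))],
                             "variance_fraction": pca.variance_fractions}),
               out, "pca_variance.tsv", report)
        perm_rows = []
        for k in (1, 2, 3):
            pc = pca.component(k)
            if len(lineages) == 2:
                r = paired_stratified_perm_test(
                    pc, samples, n_perm=th.n_perm, seed=cfg.seed + 10 + k)
                perm_rows.append(("paired_lineage", f"PC{k}", r))
            r = twosample_stratified_perm_test(
                pc, samples, n_perm=th.n_perm, seed=cfg.seed + 20 + k)
            perm_rows.append(("twosample_age", f"PC{k}", r))
        r = stratified_trend_test(pca.component(1), samples,
                                  n_perm=th.n_perm, seed=cfg.seed + 30)
        perm_rows.append(("trend_differentiation", "PC1", r))
        perm_df = pd.DataFrame([
            {"test": t, "component": c, "statistic": r.statistic, "p_value": r.p_value,
             "scheme": r.scheme, "n_arrangements": r.n_arrangements,
             "exhaustive": r.exhaustive, "seed": r.seed}
            for t, c, r in perm_rows
        ])
        _write(perm_df, out, "permutation_tests.tsv", report)

        order_rows = []
        pc1 = pca.component(1)
        gm = pc1.groupby(samples["group"]).mean()
        for lin in lineages:
            order = [f"{lin}_{subsets[1]}_old", f"{lin}_{subsets[1]}_young",
                     f"{lin}_{subsets[0]}_old", f"{lin}_{subsets[0]}_young"]
            if all(g in gm.index for g in order):
                ok, p = ordering_probability(gm.to_dict(), order)
                order_rows.append({"lineage": lin, "order": ">".join(order),
                                   "matches": ok, "p_null": p})
        if order_rows:
            _write(pd.DataFrame(order_rows), out, "ordering_probability.tsv", report)

        loading_peaks = pc_loading_peaks(pca, 1, th.n_pc_loading)

        # ---------------- clustering + motifs ----------------
        stage = "cluster_motif"
        aging_names = [f"aging_{lin}" for lin in lineages]
        sig_mask = pd.Series(False, index=counts.index)
        for name in aging_names:
            tab = diff.for_contrast(name)
            sig_mask |= (tab["q_value"] < th.q_cutoff).reindex(counts.index, fill_value=False)
        sig_peaks = sig_mask.index[sig_mask].tolist()
        report.log(f"{len(sig_peaks)} sites differentially accessible with age (q<{th.q_cutoff})")
        group_means = wm.logcpm.T.groupby(samples["group"]).mean().T
        cluster_df = None
        if len(sig_peaks) >= 20:
            Z = zscore_rows(group_means.loc[sig_peaks])
            kr = range(th.k_min, min(th.k_max, len(sig_peaks) - 1) + 1)
            cres = choose_k_gap(Z, kr, B=th.gap_b, seed=cfg.seed + 40)
            cluster_df = cres.assignments.rename("cluster").rename_axis("peak_id").reset_index()
            _write(cluster_df, out, "age_site_clusters.tsv", report)
            _write(cres.gap_curve, out, "gap_curve.tsv", report)
            report.log(f"gap statistic chose k={cres.chosen_k}")
            fc_cols = {}
            for lin in lineages:
                for sub in subsets:
                    name = f"age_{sub}_{lin}"
                    fc_cols[f"{lin}_{sub}"] = diff.for_contrast(name)["log_fc"]
            fc = pd.DataFrame(fc_cols).loc[sig_peaks]
            fg4 = fold_change_groups(fc, k=4, seed=cfg.seed + 41)
            _write(fg4.assignments.rename("group").rename_axis("peak_id").reset_index(),
                   out, "foldchange_groups.tsv", report)
        else:
            report.log("skip clustering: fewer than 20 age-significant sites")

        if motifs_ann is not None and len(motifs_ann):
            enr_frames = []
            universe = set(counts.index.astype(str))
            for lin in lineages:
                tab = diff.for_contrast(f"aging_{lin}")
                for direction, mask in (
                    ("up", (tab["q_value"] < th.q_cutoff) & (tab["log_fc"] > 0)),
                    ("down", (tab["q_value"] < th.q_cutoff) & (tab["log_fc"] < 0)),
                ):
                    fg = set(tab.index[mask].astype(str))
                    if not fg:
                        report.log(f"skip motif enrichment aging_{lin} {direction}: empty foreground")
                        continue
                    enr = motif_enrichment(fg, universe - fg, motifs_ann)
                    enr.insert(0, "comparison", f"aging_{lin}_{direction}")
                    enr_frames.append(enr)
            fg = set(map(str, loading_peaks)) & universe
            if fg:
                enr = motif_enrichment(fg, universe - fg, motifs_ann)
                enr.insert(0, "comparison", "pc1_loading")
                enr_frames.append(enr)
            if enr_frames:
                all_enr = pd.concat(enr_frames, ignore_index=True)
                _write(all_enr, out, "motif_enrichment.tsv", report)
                reduced = pd.concat(
                    [best_per_family(g).assign(comparison=c)
                     for c, g in all_enr.groupby("comparison")], ignore_index=True)
                _write(reduced, out, "motif_enrichment_families.tsv", report)
            intens_rows = []
            norm = zscore_rows(wm.logcpm)
            for motif, sub in motifs_ann.groupby("motif_id"):
                pk = [p for p in sub["peak_id"] if p in universe]
                if len(pk) < 5:
                    continue
                z = motif_intensity(norm, pk, samples["group"])
                for g, v in z.items():
                    intens_rows.append({"motif_id": motif, "group": g, "z": v})
            if intens_rows:
                _write(pd.DataFrame(intens_rows), out, "motif_intensity.tsv", report)
        else:
            report.log("skip motif analysis: no annotation supplied")

        # ---------------- gene annotation + sets ----------------
        stage = "gene_annotation_sets"
        if genes is not None:
            atlas_for_genes = atlas if atlas is not None else _atlas_from_ids(counts.index)
            pg = nearest_gene(atlas_for_genes, genes, max_dist=th.max_dist)
            _write(pg, out, "peak_genes.tsv", report)
            if gene_sets:
                background = genes["gene_id"].astype(str).tolist()
                ease_frames = []
                for lin in lineages:
                    tab = diff.for_contrast(f"aging_{lin}")
                    sig = set(tab.index[tab["q_value"] < th.q_cutoff].astype(str))
                    glist = pg.loc[pg["peak_id"].isin(sig), "gene_id"].unique().tolist()
                    if not glist:
                        continue
                    e = ease_enrichment(glist, gene_sets, background)
                    e.insert(0, "comparison", f"aging_{lin}")
                    ease_frames.append(e)
                if ease_frames:
                    _write(pd.concat(ease_frames, ignore_index=True), out,
                           "ease_enrichment.tsv", report)
                shift_rows = []
                gene_to_peak = pg.drop_duplicates("gene_id").set_index("gene_id")["peak_id"]
                for lin in lineages:
                    tab = diff.for_contrast(f"age_{subsets[0]}_{lin}")
                    vals = gene_to_peak.map(tab["log_fc"]).dropna()
                    for name, members in gene_sets.items():
                        try:
                            res = geneset_shift_test(vals, members, set_name=name)
                        except ValueError:
                            continue
                        shift_rows.append({
                            "lineage": lin, "set": name, "n_set": res.n_set,
                            "statistic": res.statistic, "p_value": res.p_value,
                            "median_set": res.median_set, "median_rest": res.median_rest,
                        })
                if shift_rows:
                    _write(pd.DataFrame(shift_rows), out, "geneset_shift_tests.tsv", report)
        else:
            report.log("skip gene annotation: no gene model supplied")
    except Exception as exc:  # noqa: BLE001 - route every stage failure
        report.log(f"ERROR in stage {stage}: {exc}")
        report.write()
        raise PipelineError(stage, exc) from exc

    report.log("pipeline complete")
    report.write()
    return report


def _atlas_from_ids(peak_ids) -> PeakAtlas:
    """Reconstruct intervals from 'chrom:start-end' ids (planted atlas case)."""
    from .atlas import GenomicInterval
    ivs = []
    for pid in peak_ids:
        chrom, span = str(pid).rsplit(":", 1)
        s, e = span.split("-")
        ivs.append(GenomicInterval(chrom, int(s), int(e)))
    return PeakAtlas(ivs, [0] * len(ivs))
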