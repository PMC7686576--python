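"""Synthetic T cell cohort generator.

Emulates the study design the analysis assumes: a 2-lineage (CD4/CD8) x
3-subset (naive < CM < EM) x 2-age-group cohort in which every donor
contributes one sample per (lineage, subset).  Counts are negative binomial
around group means on the log2 scale, shifted by planted effects plus a
per-donor, per-feature log-scale random intercept.  Planted structure:

* a differentiation axis (peaks opening/closing from naive to EM) that old
  samples shift along (the age-differentiation coupling);
* an ``age_up`` class opening with age in both lineages (bZIP-like motif
  labels);
* lineage-specific age-closing classes: ``age_down_cd8`` (NRF1-like and
  YY1-like labels) and ``age_down_cd4`` (ZBTB-like labels);
* a lineage class separating CD4 from CD8;
* synthetic ribosomal genes (51 RPL, 34 RPS, 78 MRP) placed within 10 kb of
  age_down_cd8 peaks, so ribosome-proximal accessibility closes with age in
  CD8 only.

Per-sample peak calls are the atlas intervals with each peak dropped with
probability 0.2 and ends jittered by up to 10% of the width, making the
consensus (>= 2 samples, >= 50% merge) reconstruction nontrivial.  The whole
bundle regenerates byte-identically from a `SimConfig` and its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import GenomicInterval, PeakAtlas

EFFECT_CLASSES = (
    "null", "differentiation_up", "differentiation_down",
    "age_up", "age_down_cd8", "age_down_cd4", "lineage",
)

#: motif families emitted per effect class
MOTIF_ROSTER = [
    ("BATF_like", "bZIP"), ("AP1_like", "bZIP"),
    ("TBX_like", "Tbox"),
    ("NRF1_like", "NRF1"),
    ("YY1_like", "YY1"),
    ("ZBTB_like", "ZBTB"), ("THPOK_like", "ZBTB"),
    ("ETS_like", "ETS"), ("ELK_like", "ETS"),
    ("CTCF_like", "CTCF"), ("GATA_like", "GATA"),
]

FAMILY_TARGETS = {
    "bZIP": ("age_up", "differentiation_up"),
    "Tbox": ("differentiation_up",),
    "NRF1": ("age_down_cd8",),
    "YY1": ("age_down_cd8",),
    "ZBTB": ("age_down_cd4",),
    "ETS": ("differentiation_down",),
    "CTCF": (),
    "GATA": (),
}

RIBOSOMAL_SET_SIZES = {"RPL": 51, "RPS": 34, "MRP": 78}


class SimConfigError(ValueError):
    """A configuration value violating the simulator's invariants."""


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort."""

    n_donors_young: int = 6
    n_donors_old: int = 4
    lineages: tuple[str, ...] = ("CD4", "CD8")
    subsets: tuple[str, ...] = ("naive", "CM", "EM")   # ordinal: differentiation rank
    n_peaks: int = 2000
    n_genes: int = 500
    frac_diff_peaks: float = 0.20
    frac_age_peaks_cd8: float = 0.10
    frac_age_peaks_cd4: float = 0.03
    frac_lineage_peaks: float = 0.10
    diff_logfc: float = 2.0
    age_logfc: float = 1.5
    lineage_logfc: float = 1.5
    diff_age_coupling: float = 0.25    # old samples advance along the differentiation axis
    donor_sd: float = 0.3
    dispersion: float = 0.05
    lib_size_range: tuple[int, int] = (150_000, 300_000)
    rna_lib_size_range: tuple[int, int] = (400_000, 800_000)
    motif_emission: float = 0.6
    background_emission: float = 0.05
    make_insertions: bool = False
    background_insertion_frac: float = 0.1
    chrom: str = "chrS"
    genome_size: int = 10_000_000
    peak_width_range: tuple[int, int] = (300, 800)
    min_gap: int = 200
    peak_drop_prob: float = 0.2
    jitter_frac: float = 0.1
    baseline_sd: float = 0.8
    rna_effect_scale: float = 0.5      # chromatin-to-transcript attenuation
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_donors_young", "n_donors_old", "n_peaks", "n_genes"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        for name in ("frac_diff_peaks", "frac_age_peaks_cd8", "frac_age_peaks_cd4",
                     "frac_lineage_peaks", "motif_emission", "background_emission",
                     "peak_drop_prob", "jitter_frac", "background_insertion_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} must lie in [0, 1]")
        total = self.frac_diff_peaks + self.frac_age_peaks_cd8 \
            + self.frac_age_peaks_cd4 + self.frac_lineage_peaks
        if total > 1.0:
            raise SimConfigError(
                f"effect-class fractions sum to {total:.3f} > 1; classes must be disjoint"
            )
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise SimConfigError("lib_size_range must be a positive (lo, hi) pair")
        if self.rna_lib_size_range[0] <= 0:
            raise SimConfigError("rna_lib_size_range must be positive")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if len(self.subsets) < 2:
            raise SimConfigError("subsets must list >= 2 ordinal levels")
        if self.n_genes < sum(RIBOSOMAL_SET_SIZES.values()):
            raise SimConfigError(
                f"n_genes must be >= {sum(RIBOSOMAL_SET_SIZES.values())} to host the "
                "ribosomal sets"
            )

    @property
    def group_labels(self) -> list[str]:
        return [f"{l}_{s}_{a}" for l in self.lineages for s in self.subsets
                for a in ("young", "old")]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimConfigError(f"unknown SimConfig key(s): {sorted(unknown)}")
        for key in ("lineages", "subsets", "lib_size_range", "rna_lib_size_range",
                    "peak_width_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class CohortBundle:
    """Everything one synthetic study produces, plus its ground truth."""

    config: SimConfig
    samples: pd.DataFrame            # sample, donor, lineage, subset, age_group
    atlas: PeakAtlas                 # the true (planted) peak atlas
    peak_calls: dict[str, list[GenomicInterval]]
    atac_counts: pd.DataFrame        # peaks x samples
    rna_counts: pd.DataFrame         # genes x samples
    genes: pd.DataFrame              # gene_id, symbol, chrom, tss, strand, set
    gene_sets: dict[str, list[str]]
    motifs: pd.DataFrame             # motif_id, family, peak_id
    truth: pd.DataFrame              # peak_id, effect_class, mu_<group>..., motifs
    insertions: dict[str, np.ndarray] | None = None


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_peaks
    n_diff = round(cfg.frac_diff_peaks * n)
    n_cd8 = round(cfg.frac_age_peaks_cd8 * n)
    n_cd4 = round(cfg.frac_age_peaks_cd4 * n)
    n_lin = round(cfg.frac_lineage_peaks * n)
    n_up_age = round(min(n_cd8, n_cd4) / 2)
    n_down_cd8 = n_cd8 - n_up_age
    n_down_cd4 = n_cd4 - n_up_age
    classes = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    pos = 0
    for label, count in (
        ("differentiation_up", n_diff - n_diff // 2),
        ("differentiation_down", n_diff // 2),
        ("age_up", n_up_age),
        ("age_down_cd8", n_down_cd8),
        ("age_down_cd4", n_down_cd4),
        ("lineage", n_lin),
    ):
        classes[perm[pos:pos + count]] = label
        pos += count
    return classes


def _group_means(cfg: SimConfig, classes: np.ndarray,
                 baseline: np.ndarray) -> pd.DataFrame:
    """Expected log2 relative accessibility per peak per (lineage,subset,age)."""
    n_rank = len(cfg.subsets) - 1
    mu = {}
    for lin in cfg.lineages:
        for si, sub in enumerate(cfg.subsets):
            for age in ("young", "old"):
                eff = np.zeros(cfg.n_peaks)
                rank = si / n_rank
                coupled = rank + (cfg.diff_age_coupling if age == "old" else 0.0)
                eff[classes == "differentiation_up"] += cfg.diff_logfc * coupled
                eff[classes == "differentiation_down"] -= cfg.diff_logfc * coupled
                if age == "old":
                    eff[classes == "age_up"] += cfg.age_logfc
                    if lin == "CD8":
                        eff[classes == "age_down_cd8"] -= cfg.age_logfc
                    if lin == "CD4":
                        eff[classes == "age_down_cd4"] -= cfg.age_logfc
                if lin == "CD8":
                    eff[classes == "lineage"] += cfg.lineage_logfc
                mu[f"{lin}_{sub}_{age}"] = baseline + eff
    return pd.DataFrame(mu)


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    if dispersion < 1e-9:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _place_peaks(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.peak_width_range
    widths = rng.integers(lo, hi + 1, size=cfg.n_peaks)
    slack = cfg.genome_size - int(widths.sum()) - cfg.min_gap * (cfg.n_peaks + 1)
    if slack < 0:
        raise SimConfigError("genome_size too small for n_peaks at the given widths/gaps")
    extra = rng.multinomial(slack, np.full(cfg.n_peaks + 1, 1.0 / (cfg.n_peaks + 1)))
    gaps = cfg.min_gap + extra
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], widths[:-1]]))
    return starts, starts + widths


def generate_cohort(cfg: SimConfig) -> CohortBundle:
    """Generate the full synthetic study for a validated configuration."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    donors = [f"Y{i + 1:02d}" for i in range(cfg.n_donors_young)] + \
             [f"O{i + 1:02d}" for i in range(cfg.n_donors_old)]
    ages = ["young"] * cfg.n_donors_young + ["old"] * cfg.n_donors_old
    rows = []
    for donor, age in zip(donors, ages):
        for lin in cfg.lineages:
            for si, sub in enumerate(cfg.subsets):
                rows.append({
                    "sample": f"{donor}_{lin}_{sub}", "donor": donor,
                    "lineage": lin, "subset": sub, "subset_rank": si,
                    "age_group": age, "group": f"{lin}_{sub}_{age}",
                })
    samples = pd.DataFrame(rows).set_index("sample", drop=False)

    starts, ends = _place_peaks(cfg, rng)
    intervals = [GenomicInterval(cfg.chrom, int(s), int(e))
                 for s, e in zip(starts, ends)]
    atlas = PeakAtlas(intervals, [len(samples)] * cfg.n_peaks)
    peak_ids = atlas.peak_ids

    classes = _assign_classes(cfg, rng)
    baseline = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_peaks)
    mu = _group_means(cfg, classes, baseline)

    donor_eff = {d: rng.normal(0.0, cfg.donor_sd, size=cfg.n_peaks) for d in donors}
    lib_sizes = rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1,
                             size=len(samples))
    counts = np.zeros((cfg.n_peaks, len(samples)), dtype=np.int64)
    for j, (_, s) in enumerate(samples.iterrows()):
        eta = mu[s["group"]].to_numpy() + donor_eff[s["donor"]]
        rel = np.exp2(eta)
        mean = lib_sizes[j] * rel / rel.sum()
        counts[:, j] = _nb_counts(mean, cfg.dispersion, rng)
    atac_counts = pd.DataFrame(counts, index=peak_ids, columns=list(samples.index))

    # per-sample peak calls: dropped + jittered atlas intervals
    peak_calls: dict[str, list[GenomicInterval]] = {}
    widths = ends - starts
    jit = np.floor(cfg.jitter_frac * widths).astype(int)
    for sid in samples.index:
        keep = rng.random(cfg.n_peaks) >= cfg.peak_drop_prob
        ds = rng.integers(-jit, jit + 1)
        de = rng.integers(-jit, jit + 1)
        s_new = np.maximum(starts + ds, 0)
        e_new = np.maximum(ends + de, s_new + 1)
        peak_calls[sid] = [
            GenomicInterval(cfg.chrom, int(a), int(b))
            for a, b, k in zip(s_new, e_new, keep) if k
        ]

    # motif labels: matching-class emission + uniform background emission
    motif_rows = []
    for motif_id, family in MOTIF_ROSTER:
        target = np.isin(classes, FAMILY_TARGETS[family])
        p = np.where(target, cfg.motif_emission, cfg.background_emission)
        hit = rng.random(cfg.n_peaks) < p
        for pid in np.asarray(peak_ids, dtype=object)[hit]:
            motif_rows.append({"motif_id": motif_id, "family": family, "peak_id": pid})
    motifs = pd.DataFrame(motif_rows, columns=["motif_id", "family", "peak_id"])

    # genes: ribosomal sets near age_down_cd8 peaks, the rest near other peaks
    ribo_symbols = [f"{prefix}{i + 1:02d}" for prefix, size in
                    RIBOSOMAL_SET_SIZES.items() for i in range(size)]
    down_cd8_idx = np.flatnonzero(classes == "age_down_cd8")
    other_idx = np.flatnonzero(classes != "age_down_cd8")
    rng.shuffle(down_cd8_idx)
    rng.shuffle(other_idx)

    def host_peaks(pool: np.ndarray, fallback: np.ndarray, n: int) -> np.ndarray:
        if len(pool) == 0:
            pool = fallback  # e.g. a null cohort with no planted age classes
        if n == 0:
            return np.empty(0, dtype=int)
        reps = int(np.ceil(n / len(pool)))
        return np.tile(pool, reps)[:n]

    n_other = cfg.n_genes - len(ribo_symbols)
    all_idx = np.arange(cfg.n_peaks)
    hosts = np.concatenate([
        host_peaks(down_cd8_idx, other_idx, len(ribo_symbols)),
        host_peaks(other_idx, all_idx, n_other),
    ])
    symbols = ribo_symbols + [f"GENE{i + 1:04d}" for i in range(n_other)]
    set_of = {sym: sym[:3] if sym[:3] in RIBOSOMAL_SET_SIZES else ""
              for sym in symbols}
    tss = np.empty(cfg.n_genes, dtype=np.int64)
    for gi, pi in enumerate(hosts):
        off = rng.integers(-5000, int(widths[pi]) + 5000)
        tss[gi] = max(0, int(starts[pi]) + int(off))
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame({
        "gene_id": [f"G{i + 1:04d}" for i in range(cfg.n_genes)],
        "symbol": symbols, "chrom": cfg.chrom, "tss": tss, "strand": strands,
        "set": [set_of[s] for s in symbols],
        "host_peak": [peak_ids[pi] for pi in hosts],
    })
    gene_sets = {name: genes.loc[genes["set"] == name, "gene_id"].tolist()
                 for name in RIBOSOMAL_SET_SIZES}

    # RNA counts: genes inherit an attenuated version of their host peak's effect
    gene_mu = mu.to_numpy()[hosts] * cfg.rna_effect_scale \
        + rng.normal(0.0, 1.0, size=cfg.n_genes)[:, None]
    gene_mu = pd.DataFrame(gene_mu, columns=mu.columns)
    gene_donor_eff = {d: rng.normal(0.0, cfg.donor_sd, size=cfg.n_genes)
                      for d in donors}
    rna_lib = rng.integers(cfg.rna_lib_size_range[0], cfg.rna_lib_size_range[1] + 1,
                           size=len(samples))
    rna = np.zeros((cfg.n_genes, len(samples)), dtype=np.int64)
    for j, (_, s) in enumerate(samples.iterrows()):
        eta = gene_mu[s["group"]].to_numpy() + gene_donor_eff[s["donor"]]
        rel = np.exp2(eta)
        mean = rna_lib[j] * rel / rel.sum()
        rna[:, j] = _nb_counts(mean, cfg.dispersion, rng)
    rna_counts = pd.DataFrame(rna, index=genes["gene_id"].tolist(),
                              columns=list(samples.index))

    # ground truth
    motif_by_peak = motifs.groupby("peak_id")["motif_id"].agg(";".join) \
        if not motifs.empty else pd.Series(dtype=str)
    truth = pd.DataFrame({"peak_id": peak_ids, "effect_class": classes})
    for g in mu.columns:
        truth[f"mu_{g}"] = mu[g].to_numpy()
    truth["motifs"] = truth["peak_id"].map(motif_by_peak).fillna("")

    insertions = None
    if cfg.make_insertions:
        insertions = {}
        for j, sid in enumerate(samples.index):
            c = counts[:, j]
            tot = int(c.sum())
            rep_starts = np.repeat(starts, c)
            rep_widths = np.repeat(widths, c)
            pos = rep_starts + np.floor(rng.random(tot) * rep_widths).astype(np.int64)
            n_bg = round(cfg.background_insertion_frac * tot)
            bg: list[np.ndarray] = []
            need = n_bg
            while need > 0:
                cand = rng.integers(0, cfg.genome_size, size=int(need * 1.5) + 10)
                idx = np.searchsorted(starts, cand, side="right") - 1
                inside = (idx >= 0) & (cand < ends[np.clip(idx, 0, None)])
                cand = cand[~inside][:need]
                bg.append(cand)
                need -= len(cand)
            allpos = np.concatenate([pos] + bg) if n_bg else pos
            insertions[sid] = np.sort(allpos)

    return CohortBundle(
        config=cfg, samples=samples, atlas=atlas, peak_calls=peak_calls,
        atac_counts=atac_counts, rna_counts=rna_counts, genes=genes,
        gene_sets=gene_sets, motifs=motifs, truth=truth, insertions=insertions,
    )


def write_fixture(bundle: CohortBundle, directory) -> pd.DataFrame:
    """Write the bundle as plain-text files; returns the file manifest."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest = []

    def note(name: str, n_rows: int) -> None:
        manifest.append({"file": name, "rows": n_rows})

    bundle.config.to_yaml(root / "config.yaml")
    note("config.yaml", 1)

    cols = ["sample", "donor", "lineage", "subset", "age_group"]
    bundle.samples[cols].to_csv(root / "sample_sheet.csv", index=False)
    note("sample_sheet.csv", len(bundle.samples))

    bundle.atlas.to_bed(root / "atlas.bed")
    note("atlas.bed", len(bundle.atlas))

    peak_dir = root / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for sid, ivs in bundle.peak_calls.items():
        with open(peak_dir / f"{sid}.bed", "w") as fh:
            for iv in sorted(ivs):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        note(f"peaks/{sid}.bed", len(ivs))

    if bundle.insertions is not None:
        ins_dir = root / "insertions"
        ins_dir.mkdir(exist_ok=True)
        chrom = bundle.config.chrom
        for sid, pos in bundle.insertions.items():
            with open(ins_dir / f"{sid}.bed", "w") as fh:
                for p in pos:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")
            note(f"insertions/{sid}.bed", len(pos))

    bundle.atac_counts.rename_axis("peak_id").to_csv(root / "atac_counts.tsv", sep="\t")
    note("atac_counts.tsv", len(bundle.atac_counts))
    bundle.rna_counts.rename_axis("gene_id").to_csv(root / "rna_counts.tsv", sep="\t")
    note("rna_counts.tsv", len(bundle.rna_counts))
    bundle.genes.to_csv(root / "genes.tsv", sep="\t", index=False)
    note("genes.tsv", len(bundle.genes))
    bundle.motifs.to_csv(root / "motifs.tsv", sep="\t", index=False)
    note("motifs.tsv", len(bundle.motifs))
    bundle.truth.to_csv(root / "truth.tsv", sep="\t", index=False)
    note("truth.tsv", len(bundle.truth))

    from .genes import write_gmt
    write_gmt(bundle.gene_sets, root / "gene_sets.gmt")
    note("gene_sets.gmt", len(bundle.gene_sets))

    mf = pd.DataFrame(manifest)
    mf.to_csv(root / "manifest.tsv", sep="\t", index=False)
    return mf


def read_fixture(directory) -> CohortBundle:
    """Re-load a written fixture (inverse of :func:`write_fixture`)."""
    from .atlas import read_peak_beds
    from .genes import read_gmt

    root = Path(directory)
    cfg = SimConfig.from_yaml(root / "config.yaml")
    samples = pd.read_csv(root / "sample_sheet.csv")
    samples["subset_rank"] = samples["subset"].map(
        {s: i for i, s in enumerate(cfg.subsets)})
    samples["group"] = samples["lineage"] + "_" + samples["subset"] + "_" + \
        samples["age_group"]
    samples = samples.set_index("sample", drop=False)
    atlas = PeakAtlas.from_bed(root / "atlas.bed")
    sids = samples["sample"].tolist()
    peak_calls = read_peak_beds([root / "peaks" / f"{s}.bed" for s in sids], sids)
    atac = pd.read_csv(root / "atac_counts.tsv", sep="\t", index_col=0).rename_axis(None)
    rna = pd.read_csv(root / "rna_counts.tsv", sep="\t", index_col=0).rename_axis(None)
    genes = pd.read_csv(root / "genes.tsv", sep="\t",
                        dtype={"gene_id": str, "symbol": str, "chrom": str},
                        keep_default_na=False)
    motifs = pd.read_csv(root / "motifs.tsv", sep="\t", dtype=str)
    truth = pd.read_csv(root / "truth.tsv", sep="\t", keep_default_na=False)
    gene_sets = read_gmt(root / "gene_sets.gmt")
    insertions = None
    ins_dir = root / "insertions"
    if ins_dir.is_dir():
        insertions = {}
        for sid in sids:
            df = pd.read_csv(ins_dir / f"{sid}.bed", sep="\t", header=None,
                             names=["chrom", "start", "end"])
            insertions[sid] = df["start"].to_numpy(dtype=np.int64)
    return CohortBundle(
        config=cfg, samples=samples, atlas=atlas, peak_calls=peak_calls,
        atac_counts=atac, rna_counts=rna, genes=genes, gene_sets=gene_sets,
        motifs=motifs, truth=truth, insertions=insertions,
    )
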