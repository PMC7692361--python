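"""End-to-end orchestration: simulate -> windows -> filter -> classify ->
reconstruct -> gene fate -> constraint, with a reproducible run directory.

The default configuration simulates a 10 Mb Z-like chromosome of 200 windows
(50 kb) carrying a terminal PAR, a 1.3 Mb ZTR hosting nine transposed genes
and a nested 150 kb W-deletion, a 100 kb Z-linked duplication, and a
hemizygous background, plus a 1 Mb diploid baseline chromosome used for
depth normalization and background SNP density.  All stages are
deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constraint_expression as ce
from . import coverage_windows as cw
from . import gene_fate as gf
from . import region_classify as rc
from . import synthetic_data as sd
from . import variant_filter as vf
from . import w_reconstruct as wr

__all__ = ["RunConfig", "PipelineResult", "default_layouts", "run_pipeline",
           "evaluate_against_truth"]


MB = 1_000_000
KB = 1_000


def default_layouts(window_size: int = 50_000) -> tuple[sd.SimLayout, sd.SimLayout]:
    """The bundled study layout: focal chrZ and a diploid baseline chrA.

    chrZ (10 Mb): PAR [0, 0.5 Mb); ZTR [2.0, 3.3 Mb) with a 150 kb W-deletion
    [2.45, 2.6 Mb); Z_DUP [5.0, 5.1 Mb); hemizygous Z elsewhere.  Nine genes
    sit in the ZTR: five wholly inside the deletion, two straddling its
    edges, and two surviving genes (ANXA1-like and ALDH1A1-like).
    """
    genes = [
        sd.GeneSpec("ANXA1", 2_050_000, 2_056_000, "+",
                    cds=((2_051_000, 2_052_998),)),
        sd.GeneSpec("TMC1", 2_430_000, 2_460_000, "+",
                    cds=((2_431_000, 2_433_400),)),
        sd.GeneSpec("ZFAND5", 2_460_000, 2_472_000, "+",
                    cds=((2_461_000, 2_462_200),)),
        sd.GeneSpec("TRPM3", 2_475_000, 2_495_000, "-",
                    cds=((2_476_000, 2_479_000),)),
        sd.GeneSpec("TMEM2", 2_500_000, 2_512_000, "+",
                    cds=((2_501_000, 2_504_399),)),
        sd.GeneSpec("GDA", 2_520_000, 2_530_000, "+",
                    cds=((2_521_000, 2_522_299),)),
        sd.GeneSpec("C9orf85", 2_540_000, 2_548_000, "-",
                    cds=((2_541_000, 2_541_501),)),
        sd.GeneSpec("FRMD3", 2_580_000, 2_620_000, "+",
                    cds=((2_581_000, 2_583_001),)),
        sd.GeneSpec("ALDH1A1", 3_100_000, 3_108_000, "+",
                    cds=((3_101_000, 3_102_500),)),
    ]
    chrz = sd.SimLayout(
        chrom_name="chrZ",
        chrom_length=10 * MB,
        window_size=window_size,
        regions=[
            sd.RegionSpec(0, 500 * KB, "PAR"),
            sd.RegionSpec(500 * KB, 2_000 * KB, "HEMIZYGOUS_Z"),
            sd.RegionSpec(2_000 * KB, 3_300 * KB, "ZTR"),
            sd.RegionSpec(3_300 * KB, 5_000 * KB, "HEMIZYGOUS_Z"),
            sd.RegionSpec(5_000 * KB, 5_100 * KB, "Z_DUP"),
            sd.RegionSpec(5_100 * KB, 10_000 * KB, "HEMIZYGOUS_Z"),
        ],
        w_deletions=[(2_450 * KB, 2_600 * KB)],
        genes=genes,
    )
    chra = sd.SimLayout(
        chrom_name="chrA",
        chrom_length=1 * MB,
        window_size=window_size,
        regions=[sd.RegionSpec(0, 1 * MB, "AUTOSOME_LIKE")],
    )
    return chrz, chra


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the standard hard-filter
    thresholds and the bundled synthetic study conditions."""

    seed: int = 0
    window_size: int = 50_000
    params: sd.SimParams = None  # type: ignore[assignment]
    classify: rc.ClassifyParams = None  # type: ignore[assignment]
    thresholds: vf.HardFilterThresholds = field(default_factory=vf.HardFilterThresholds)
    af_bounds: tuple[float, float] = (0.3, 0.7)
    bias_fold_threshold: float = 2.0
    write_depth: bool = False
    # constraint stage: per-surviving-gene W-branch omega used for the codon
    # simulation (the Z branch uses 0.5 everywhere)
    omega_w: dict = field(default_factory=lambda: {"ANXA1": 0.0, "ALDH1A1": 0.5})
    n_codons: int = 600

    def __post_init__(self):
        if self.params is None:
            self.params = sd.SimParams(seed=self.seed)
        if self.classify is None:
            self.classify = rc.ClassifyParams()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(seed=int(raw.get("seed", 0)))
        if "window_size" in raw:
            cfg.window_size = int(raw["window_size"])
        if "params" in raw:
            cfg.params = sd.SimParams(seed=cfg.seed, **raw["params"])
        else:
            cfg.params = sd.SimParams(seed=cfg.seed)
        if "classify" in raw:
            cfg.classify = rc.ClassifyParams(**raw["classify"])
        if "thresholds" in raw:
            cfg.thresholds = vf.HardFilterThresholds(**raw["thresholds"])
        for key in ("af_bounds", "bias_fold_threshold", "write_depth",
                    "omega_w", "n_codons"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.af_bounds = tuple(cfg.af_bounds)
        return cfg


@dataclass
class PipelineResult:
    config: RunConfig
    windows: pd.DataFrame
    calls: list
    deletion_sets: list
    fates: list
    fate_summary: dict
    dnds: pd.DataFrame
    hi: pd.DataFrame
    expression_bias: pd.DataFrame
    rank_sum: dict
    truth: dict
    summary_text: str
    outdir: Path | None = None


def run_pipeline(config: RunConfig, outdir=None,
                 layouts: tuple[sd.SimLayout, sd.SimLayout] | None = None
                 ) -> PipelineResult:
    """Run the full detection and characterization pipeline on synthetic data.

    ``layouts`` overrides the bundled (focal, baseline) chromosome pair.
    """
    chrz, chra = layouts if layouts is not None else default_layouts(config.window_size)
    params = replace(config.params, seed=config.seed)
    params_a = replace(params, seed=(config.seed * 9973 + 17) & 0x7FFFFFFF)

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    ref_z = sd.simulate_reference(chrz, params)
    ref_a = sd.simulate_reference(chra, params_a)
    truth = dict(ref_z.truth)

    depth = {}
    variants = {}
    provenance = {}
    for sex in sd.SEXES:
        dz = sd.simulate_depth(chrz, params, sex)
        da = sd.simulate_depth(chra, params_a, sex)
        depth[sex] = pd.concat([dz, da], ignore_index=True)
        depth[sex]["chrom"] = depth[sex]["chrom"].astype("category")
        vz, pz = sd.simulate_variants(ref_z, sex)
        va, pa = sd.simulate_variants(ref_a, sex)
        variants[sex] = pd.concat([vz, va], ignore_index=True)
        provenance[sex] = pd.concat([pz, pa], ignore_index=True)

    contigs = {chrz.chrom_name: chrz.chrom_length, chra.chrom_name: chra.chrom_length}
    if out is not None:
        sd.write_fasta(chrz.chrom_name, ref_z.sequence, out / "reference_chrZ.fa")
        sd.write_gff3(chrz, out / "genes_chrZ.gff3")
        sd.write_truth(truth, out / "truth.yaml")
        for sex in sd.SEXES:
            sd.write_vcf(variants[sex], out / f"variants_{sex}.vcf", contigs, sample=sex)
            if config.write_depth:
                sd.write_depth(depth[sex], out / f"depth_{sex}.tsv")

    # --- windows ----------------------------------------------------------
    chrom_lengths = dict(contigs)
    win = {}
    for sex in sd.SEXES:
        sites, _ = cw.site_filter(depth[sex])
        w = cw.window_coverage(sites, config.window_size, chrom_lengths)
        baseline = (w["chrom"] == chra.chrom_name).to_numpy()
        win[sex] = cw.normalize_coverage(w, baseline)

    # --- variants ---------------------------------------------------------
    retained = {}
    for sex in sd.SEXES:
        rec = variants[sex].sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        rec = vf.hard_filter(rec, config.thresholds)
        kept, _ = vf.allele_fraction_filter(rec, *config.af_bounds)
        retained[sex] = kept
        win[sex] = vf.snp_density(kept, win[sex],
                                  "f" if sex == "female" else "m")
    # each sex table needs both density columns for classification
    fwin = vf.snp_density(retained["male"], win["female"], "m")
    mwin = vf.snp_density(retained["female"], win["male"], "f")

    # --- classify ---------------------------------------------------------
    cpar = config.classify
    baseline_mask = (fwin["chrom"] == chra.chrom_name).to_numpy()
    lam_f, lam_m = rc.estimate_background_density(fwin, baseline_mask)
    cpar = replace(cpar, lambda_bg_f=lam_f, lambda_bg_m=lam_m)
    labelled = rc.classify_windows(fwin, mwin, cpar,
                                   baseline_chroms={chra.chrom_name})
    calls = rc.merge_calls(labelled, cpar)

    ztr_calls = [c for c in calls if c.label == "ZTR"]
    rank_sum = {}
    zmask = np.zeros(len(labelled), dtype=bool)
    for c in ztr_calls:
        m = ((labelled["chrom"] == c.chrom) &
             (labelled["start"] >= c.start) &
             (labelled["end"] <= c.end)).to_numpy()
        # candidate W-deletion windows carry no W-derived signal; keep them
        # out of the density contrast
        for ds, de in c.interior_candidates:
            m &= ~((labelled["chrom"] == c.chrom) &
                   (labelled["start"] >= ds) &
                   (labelled["end"] <= de)).to_numpy()
        zmask |= m
    ok = (~labelled["excluded"]).to_numpy()
    if zmask.any():
        inside = labelled.loc[zmask & ok, "f_density"].to_numpy()
        outside = labelled.loc[~zmask & ok, "f_density"].to_numpy()
        u, p = rc.rank_sum_test(inside, outside, "greater")
        rank_sum["ztr_female_vs_rest_female"] = p
        u, p = rc.rank_sum_test(inside, labelled.loc[zmask & ok, "m_density"].to_numpy(),
                                "greater")
        rank_sum["ztr_female_vs_ztr_male"] = p

    # --- reconstruct + gene fates ----------------------------------------
    genes = [gf.GeneModel(g.name, chrz.chrom_name, g.start, g.end, g.strand, g.cds)
             for g in chrz.genes]
    deletion_sets = []
    fates = []
    for call in ztr_calls:
        dels = wr.call_w_deletions(call, cpar.min_run, config.window_size)
        deletion_sets.append(dels)
        fvars = retained["female"]
        sub = fvars[(fvars["chrom"] == call.chrom) &
                    (fvars["pos"] - 1 >= call.start) &
                    (fvars["pos"] - 1 + fvars["ref"].str.len() <= call.end)]
        wps = wr.build_w_pseudosequence(ref_z.sequence, (call.start, call.end), sub)
        in_env = [g for g in genes if g.start >= call.start and g.end <= call.end]
        fates.extend(gf.classify_gene_fates(in_env, wps, dels, ref_z.sequence))
        if out is not None:
            sd.write_fasta(
                f"W_ZTR_{call.chrom}_{call.start}_{call.end}"
                f"|variants={len(wps.applied_variants)}",
                wps.sequence, out / f"w_pseudo_{call.start}.fa")
            wps.coord_map.to_frame().to_csv(out / f"coord_map_{call.start}.tsv",
                                            sep="\t", index=False)

    fate_table, fate_totals = (pd.DataFrame(), {})
    if fates:
        fate_table, fate_totals = gf.summarize_fates({"focal": fates})

    # --- constraint / expression -----------------------------------------
    survivors = [f.name for f in fates if f.fate == "intact"]
    dnds_rows = []
    for i, gene in enumerate(sorted(config.omega_w)):
        om_w = float(config.omega_w[gene])
        # the outgroup lineage shares the gene-wide constraint of the W copy
        sim = sd.simulate_codon_alignment(
            config.n_codons,
            {"outgroup": (0.06, om_w), "ancestor": (0.0, 1.0),
             "Z": (0.02, 0.5), "W": (0.02, om_w)},
            seed=(config.seed * 31 + i) & 0x7FFFFFFF)
        rates = ce.branch_rates(sim.alignment)
        for br in ("Z", "W"):
            r = rates[br]
            dnds_rows.append({
                "gene": gene, "branch": br, "sd": r.sd, "nd": r.nd,
                "S": r.S, "N": r.N, "dS": r.dS, "dN": r.dN,
                "omega": r.omega, "omega_defined": r.omega_defined,
                "true_syn": sim.truth[br]["syn"],
                "true_nonsyn": sim.truth[br]["nonsyn"],
            })
    dnds = pd.DataFrame(dnds_rows)

    all_gene_names = [g.name for g in chrz.genes]
    background = [f"ZGENE{i:03d}" for i in range(300)]
    hi_table = sd.simulate_hi_scores(background + all_gene_names,
                                     high_genes=survivors, seed=config.seed)
    hi, _ = ce.hi_percentile(hi_table, background, sorted(config.omega_w))

    expr = sd.simulate_expression(all_gene_names, biased_genes=("ANXA1",),
                                  seed=config.seed)
    _, bias = ce.expression_profile(expr, config.bias_fold_threshold)

    # --- summary ----------------------------------------------------------
    summary = _summarize(config, cpar, calls, deletion_sets, fates,
                         fate_totals, rank_sum, dnds, hi, bias)
    if out is not None:
        labelled.to_csv(out / "windows.tsv", sep="\t", index=False)
        _write_calls(calls, out / "regions.bed")
        if fates:
            pd.DataFrame([f.__dict__ for f in fates]).to_csv(
                out / "gene_fates.tsv", sep="\t", index=False)
        dnds.to_csv(out / "dnds.tsv", sep="\t", index=False)
        hi.to_csv(out / "hi_percentiles.tsv", sep="\t", index=False)
        bias.to_csv(out / "expression_bias.tsv", sep="\t", index=False)
        (out / "summary.txt").write_text(summary)

    return PipelineResult(
        config=config, windows=labelled, calls=calls,
        deletion_sets=deletion_sets, fates=fates, fate_summary=fate_totals,
        dnds=dnds, hi=hi, expression_bias=bias, rank_sum=rank_sum,
        truth=truth, summary_text=summary, outdir=out)


def _write_calls(calls, path):
    with open(path, "w") as fh:
        for c in calls:
            ev = json.dumps(c.evidence, sort_keys=True)
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.label}\t{c.n_windows}\t{ev}\n")


def _summarize(config, cpar, calls, deletion_sets, fates, fate_totals,
               rank_sum, dnds, hi, bias) -> str:
    lines = ["# ztr-scan run summary", ""]
    lines.append(f"seed: {config.seed}")
    lines.append(f"window_size: {config.window_size}")
    lines.append(f"haploid_depth: {config.params.haploid_depth}")
    lines.append(f"zw_divergence: {config.params.zw_divergence}")
    lines.append(f"background_het: {config.params.background_het}")
    lines.append(f"lambda_bg: f={cpar.lambda_bg_f:.3f} m={cpar.lambda_bg_m:.3f}")
    lines.append("")
    lines.append("## region calls")
    for c in calls:
        if c.label in ("UNCLASSIFIED",):
            continue
        lines.append(f"{c.chrom}:{c.start}-{c.end}\t{c.label}\t{c.n_windows} windows")
    lines.append("")
    for d in deletion_sets:
        s = d.summary()
        lines.append("## W-deletion accounting")
        lines.append(f"envelope {s['envelope_bp']} bp; deleted {s['deleted_bp']} bp; "
                     f"retained {s['retained_bp']} bp ({s['retained_mb']} Mb)")
    if fates:
        lines.append("")
        lines.append("## gene fates")
        for f in sorted(fates, key=lambda f: f.name):
            cause = f" ({f.pseudogene_cause})" if f.fate == "pseudogene" else ""
            lines.append(f"{f.name}\t{f.fate}{cause}")
        lines.append(f"total {fate_totals['total_genes']} genes, "
                     f"functional {fate_totals['functional']}, "
                     f"percent lost {fate_totals['percent_lost']}%")
    if rank_sum:
        lines.append("")
        lines.append("## rank-sum tests (one-sided)")
        for k, v in sorted(rank_sum.items()):
            lines.append(f"{k}: p = {v:.3g}")
    if len(dnds):
        lines.append("")
        lines.append("## branch dN/dS")
        for row in dnds.itertuples():
            om = f"{row.omega:.3f}" if row.omega is not None and not pd.isna(row.omega) \
                else "undef"
            lines.append(f"{row.gene}\t{row.branch}\tsd={row.sd:.1f} nd={row.nd:.1f} "
                         f"omega={om}")
    if len(hi):
        lines.append("")
        lines.append("## haploinsufficiency percentiles")
        for row in hi.itertuples():
            lines.append(f"{row.gene}\t{row.percentile:.1f}")
    if len(bias):
        flagged = bias[bias["gonad_bias"] == True]  # noqa: E712
        lines.append("")
        lines.append("## female-gonad expression bias")
        lines.append("biased: " + (", ".join(sorted(flagged["gene"])) or "none"))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------


def evaluate_against_truth(result: PipelineResult) -> dict:
    """Compare pipeline output with the planted truth of its synthetic run.

    Returns window-label accuracy (over retained focal-chromosome windows),
    the worst envelope boundary offset (in windows) over planted non-background
    regions, and the worst W-deletion boundary offset.
    """
    truth = result.truth
    chrom = truth["chrom"]
    wsize = truth["window_size"]
    labelled = result.windows
    focal = labelled[labelled["chrom"] == chrom].reset_index(drop=True)
    truth_labels = truth["window_labels"]

    # per-window accuracy: a window inside a planted ZTR (including its
    # W-deletion windows) should end up inside a recovered ZTR call
    final = list(focal["label"])
    for c in result.calls:
        if c.chrom != chrom:
            continue
        for i in range(c.start // wsize, c.end // wsize):
            final[i] = c.label
    ok = (~focal["excluded"]).to_numpy()
    n_match = sum(1 for i in range(len(truth_labels))
                  if ok[i] and final[i] == truth_labels[i])
    accuracy = 100.0 * n_match / max(int(ok.sum()), 1)

    # planted region envelopes
    max_offset = 0
    unrecovered = []
    for start, end, label in truth["regions"]:
        if label in ("HEMIZYGOUS_Z", "AUTOSOME_LIKE"):
            continue
        hits = [c for c in result.calls
                if c.chrom == chrom and c.label == label and
                c.start < end and start < c.end]
        if not hits:
            unrecovered.append([start, end, label])
            continue
        best = max(hits, key=lambda c: min(c.end, end) - max(c.start, start))
        off = max(abs(best.start - start), abs(best.end - end)) / wsize
        max_offset = max(max_offset, off)

    # planted W-deletions
    del_offset = None
    if truth["w_deletions"]:
        del_offset = 0.0
        recovered = [iv for ds in result.deletion_sets for iv in ds.deletions]
        for ds, de in truth["w_deletions"]:
            hits = [d for d in recovered if d[0] < de and ds < d[1]]
            if not hits:
                del_offset = float("inf")
                continue
            best = max(hits, key=lambda d: min(d[1], de) - max(d[0], ds))
            del_offset = max(del_offset,
                             max(abs(best[0] - ds), abs(best[1] - de)) / wsize)

    # exact retained-length bookkeeping
    bookkeeping_exact = all(
        ds.retained_length + ds.total_deleted == ds.envelope_length
        for ds in result.deletion_sets)

    return {
        "window_accuracy_percent": accuracy,
        "max_envelope_offset_windows": max_offset,
        "unrecovered_regions": unrecovered,
        "max_deletion_offset_windows": del_offset,
        "bookkeeping_exact": bookkeeping_exact,
    }
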