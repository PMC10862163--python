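"""End-to-end analysis: data -> QC -> two relatedness matrices -> two fits.

The pipeline mirrors the analysis order of a pedigree-vs-genomic
heritability comparison: obtain (or simulate) pedigree, genotypes and
phenotypes; apply marker QC; build the pedigree A matrix (dummy parents
inserted, trimmed to genotyped individuals with ancestral links projected)
and the genomic relatedness matrix; compare the matrices with a Mantel
test; classify social father–offspring pairs into within-pair vs
extra-pair; fit the animal model once with each matrix; and report the
variance components side by side with the credible-interval-overlap
decision rule.

Every random draw derives from the single run seed through fixed stream
offsets (simulation uses the seed itself, the Mantel test seed+11, the P
and G model fits seed+21 and seed+22), so identical configurations
reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .animal_model import (
    ModelSpec,
    PosteriorDraws,
    fit_animal_model,
    genetic_coefficient,
    summarize_heritability,
    summarize_model,
)
from .errors import InvalidConfigError
from .relatedness import (
    MantelResult,
    PaternityResult,
    RelatednessMatrix,
    a_matrix_for,
    build_grm_ibs,
    build_grm_vanraden,
    classify_paternity,
    insert_dummy_parents,
    mantel_correlation,
    pedigree_summary,
    trim_to_common,
)
from .simulate import SimConfig, simulate_all
from .snpqc import QCResult, apply_qc

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    hwe_alpha: float = 0.001
    maf_min: float = 0.05
    snp_missing_max: float = 0.1
    indiv_missing_max: float = 0.05
    excluded_chromosomes: tuple = ("X", "Y", "Z", "W", "XY")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``mode`` is either ``synthetic`` (simulate from ``sim``) or ``files``
    (read the given paths).  ``grm_method`` selects the genomic matrix used
    for model fitting and paternity classification: the centred
    ``vanraden`` construction (default; same additive-relationship scale as
    the pedigree A, which the paternity thresholds and the Va comparison
    presuppose) or raw ``ibs`` allele sharing.
    """

    mode: str = "synthetic"
    seed: int = 0
    out_dir: str = "pedgrm_run"
    sim: SimConfig = field(default_factory=SimConfig)
    pedigree_path: str | None = None
    genotype_ped: str | None = None
    genotype_map: str | None = None
    genotype_csv: str | None = None
    phenotype_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    epp_high: float = 0.3
    epp_low: float = 0.1
    grm_method: str = "vanraden"
    mantel_permutations: int = 999
    mantel_bootstrap: int = 500
    n_iter: int = 5000
    n_burnin: int = 1000
    n_chains: int = 4
    thin: int = 1
    include_year: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise InvalidConfigError("mode must be 'synthetic' or 'files'")
        if self.grm_method not in ("vanraden", "ibs"):
            raise InvalidConfigError("grm_method must be 'vanraden' or 'ibs'")
        if self.mode == "files":
            has_plink = self.genotype_ped and self.genotype_map
            if not (self.pedigree_path and self.phenotype_path
                    and (has_plink or self.genotype_csv)):
                raise InvalidConfigError(
                    "files mode needs pedigree, phenotype and genotype paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qc = QCThresholds(**raw.pop("qc", {}))
        cfg = cls(sim=sim, qc=qc, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["sim"]["measurer_effects"] = list(out["sim"]["measurer_effects"])
        out["qc"]["excluded_chromosomes"] = list(out["qc"]["excluded_chromosomes"])
        return out


@dataclass
class ComparisonReport:
    """Everything the run computed, with the CrI-overlap decision rule."""

    table1: str
    p_summary: pd.DataFrame
    g_summary: pd.DataFrame
    h2_p: tuple
    h2_g: tuple
    gc_p: tuple
    gc_g: tuple
    va_p: tuple
    va_g: tuple
    vpe_p: tuple
    vpe_g: tuple
    mantel: MantelResult
    paternity_counts: dict
    pedigree_before: dict
    pedigree_after: dict
    qc_attrition: list
    h2_cri_overlap: bool
    va_cri_overlap: bool
    prob_va_g_gt_p: float
    trait_mean: float
    n_obs: int
    n_individuals: int
    artifacts: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def tup(t):
            return {"mean": t[0], "lower": t[1], "upper": t[2]}

        return {
            "n_obs": self.n_obs,
            "n_individuals": self.n_individuals,
            "trait_mean": self.trait_mean,
            "mantel": {"r": self.mantel.r, "p": self.mantel.p_value,
                       "ci": list(self.mantel.ci)},
            "epp": self.paternity_counts,
            "pedigree_summary_full": self.pedigree_before,
            "pedigree_summary_trimmed": self.pedigree_after,
            "qc_attrition": [list(x) for x in self.qc_attrition],
            "h2": {"P": tup(self.h2_p), "G": tup(self.h2_g),
                   "cri_overlap": self.h2_cri_overlap},
            "Va": {"P": tup(self.va_p), "G": tup(self.va_g),
                   "cri_overlap": self.va_cri_overlap,
                   "prob_G_gt_P": self.prob_va_g_gt_p},
            "Vpe": {"P": tup(self.vpe_p), "G": tup(self.vpe_g)},
            "genetic_coefficient": {"P": tup(self.gc_p), "G": tup(self.gc_g)},
            "artifacts": self.artifacts,
        }


# ---------------------------------------------------------------------------
# Table 1 style formatting
# ---------------------------------------------------------------------------

_TABLE1_VARIANCE_ROWS = [
    ("Additive genetic", "Va"),
    ("Permanent environment", "Vpe"),
    ("Residual", "Vres"),
    ("Heritability", "h2"),
    ("Genetic coefficient", "genetic_coefficient"),
]


def _pretty_fixed(name: str) -> str:
    m = re.fullmatch(r"measurerm?(\w+)", name)
    return f"Measurer{m.group(1)}" if m else name


def format_table1(summaries: dict) -> str:
    """Two-column ("P", "G") variance-component table, values at 2 dp.

    ``summaries`` maps a column name to a dict of row label ->
    (mean, lower, upper); a missing column gets a placeholder, but a
    column missing one of the required variance rows is an error.
    """
    columns = ["P", "G"]
    required = [label for label, _ in _TABLE1_VARIANCE_ROWS]
    fixed_rows: list[str] = []
    for col in columns:
        if col not in summaries:
            continue
        missing = [r for r in required if r not in summaries[col]]
        if missing:
            raise ValueError(f"column {col!r} lacks required rows: {missing}")
        for row in summaries[col]:
            if row not in required and row not in fixed_rows:
                fixed_rows.append(row)

    def cell(col, row):
        if col not in summaries or row not in summaries[col]:
            return "—"
        mean, lo, hi = summaries[col][row]
        return f"{mean:.2f} ({lo:.2f}, {hi:.2f})"

    width = 28
    lines = [f"{'':{width}}{'P':>24}{'G':>24}"]
    if fixed_rows:
        lines.append("Fixed effects")
        for row in fixed_rows:
            lines.append(f"{row:{width}}{cell('P', row):>24}{cell('G', row):>24}")
    lines.append("Random effects")
    for row in required[:3]:
        lines.append(f"{row:{width}}{cell('P', row):>24}{cell('G', row):>24}")
    for row in required[3:]:
        lines.append(f"{row:{width}}{cell('P', row):>24}{cell('G', row):>24}")
    return "\n".join(lines)


def parse_table1(text: str) -> dict:
    """Inverse of :func:`format_table1` (means and CrIs at printed precision)."""
    out: dict = {"P": {}, "G": {}}
    pat = re.compile(r"(-?\d+\.\d+) \((-?\d+\.\d+), (-?\d+\.\d+)\)")
    for line in text.splitlines()[1:]:
        cells = pat.findall(line)
        if not cells:
            continue
        label = line[:28].strip() or line.split("  ")[0].strip()
        for col, cell in zip(("P", "G")[:len(cells)], cells):
            out[col][label] = tuple(float(v) for v in cell)
    return out


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _column_summaries(draws: PosteriorDraws, trait_mean: float) -> dict:
    table = summarize_model(draws)
    col = {}
    for row in table.itertuples(index=False):
        if row.parameter == "mu" or row.parameter.startswith("V"):
            continue
        if row.parameter == "h2":
            col["Heritability"] = (row.mean, row.lower, row.upper)
        else:
            col[_pretty_fixed(row.parameter)] = (row.mean, row.lower, row.upper)
    for label, param in _TABLE1_VARIANCE_ROWS[:3]:
        sub = table[table["parameter"] == param]
        if len(sub):
            r = sub.iloc[0]
            col[label] = (r["mean"], r["lower"], r["upper"])
    gc = genetic_coefficient(draws, trait_mean)
    col["Genetic coefficient"] = (gc.mean, gc.lower, gc.upper)
    # order rows: fixed effects first, then the canonical variance rows
    ordered = {k: v for k, v in col.items()
               if k not in dict(_TABLE1_VARIANCE_ROWS)}
    for label, _ in _TABLE1_VARIANCE_ROWS:
        if label in col:
            ordered[label] = col[label]
    return ordered


def _overlap(lo1, hi1, lo2, hi2) -> bool:
    return not (lo1 > hi2 or lo2 > hi1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Execute every stage and write all intermediates under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    log_lines: list[str] = []

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        log_lines.append(f"artifact\t{name}\tsha256:{artifacts[name]}")
        return path

    # -- stage 1: inputs --------------------------------------------------
    if config.mode == "synthetic":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        pedigree, genotypes, phenotypes, truth = simulate_all(sim)
        save("pedigree_social.csv", lambda p: pio.write_pedigree_csv(pedigree, p))
        save("pedigree_genetic.csv",
             lambda p: pio.write_pedigree_csv(pedigree, p, which="genetic"))
        save("genotypes.ped",
             lambda p: pio.write_plink(genotypes, p, out / "genotypes.map", pedigree))
        artifacts["genotypes.map"] = _sha256(out / "genotypes.map")
        save("genotypes.csv", lambda p: pio.write_dosage_csv(genotypes, p))
        save("phenotypes.csv", lambda p: pio.write_phenotypes_csv(phenotypes, p))
        save("truth.csv", lambda p: truth.to_csv(p, index=False))
    else:
        pedigree = pio.read_pedigree_csv(config.pedigree_path)
        if config.genotype_ped:
            genotypes = pio.read_plink(config.genotype_ped, config.genotype_map)
        else:
            genotypes = pio.read_dosage_csv(config.genotype_csv, config.genotype_map)
        phenotypes = pio.read_phenotypes_csv(config.phenotype_path)
    log_lines.append(f"stage\tinputs\tn_ped={len(pedigree)}\t"
                     f"n_geno={genotypes.n_individuals}x{genotypes.n_loci}\t"
                     f"n_phen={len(phenotypes)}")

    # -- stage 2: marker QC ----------------------------------------------
    qc: QCResult = apply_qc(
        genotypes,
        hwe_alpha=config.qc.hwe_alpha,
        maf_min=config.qc.maf_min,
        snp_missing_max=config.qc.snp_missing_max,
        indiv_missing_max=config.qc.indiv_missing_max,
        excluded_chromosomes=set(config.qc.excluded_chromosomes),
    )
    save("qc_locus_report.csv", lambda p: qc.locus_report.to_csv(p, index=False))
    save("qc_individual_report.csv",
         lambda p: qc.individual_report.to_csv(p, index=False))
    log_lines.append(f"stage\tqc\tattrition={qc.attrition}\t"
                     f"kept={qc.n_individuals_kept}x{qc.n_loci_kept}")

    # -- stage 3: relatedness matrices ------------------------------------
    ped_dummied = insert_dummy_parents(pedigree)
    phen_ids = [str(i) for i in pd.unique(phenotypes["id"].map(str))]
    genotyped = set(qc.genotypes.ids)
    common = [i for i in phen_ids if i in genotyped]
    if not common:
        raise InvalidConfigError("no individuals with both genotypes and phenotypes")
    summary_full = pedigree_summary(ped_dummied)
    A = a_matrix_for(ped_dummied, common)
    ped_trimmed = trim_to_common(ped_dummied, common)
    summary_trim = pedigree_summary(ped_trimmed)
    builder = build_grm_vanraden if config.grm_method == "vanraden" else build_grm_ibs
    G_full = builder(qc.genotypes)
    G = trim_to_common(G_full, common)
    save("relmat_pedigree.csv", lambda p: pio.write_relatedness_csv(A, p))
    save("relmat_genomic.csv", lambda p: pio.write_relatedness_csv(G, p))
    log_lines.append(f"stage\trelatedness\tn_common={len(common)}\t"
                     f"grm_method={config.grm_method}")

    # -- stage 4: matrix comparison and paternity -------------------------
    mantel = mantel_correlation(A, G, n_perm=config.mantel_permutations,
                                seed=config.seed + 11,
                                n_boot=config.mantel_bootstrap)
    pairs = [(r.sire, r.id) for r in pedigree.links("social").itertuples(index=False)
             if r.sire is not None and r.sire in genotyped and r.id in genotyped]
    paternity: PaternityResult = classify_paternity(
        G_full, pairs, high=config.epp_high, low=config.epp_low)
    save("paternity.csv", lambda p: paternity.assignments.to_csv(p, index=False))
    log_lines.append(f"stage\tcomparison\tmantel_r={mantel.r:.4f}\t"
                     f"epp={paternity.n_epp}/{paternity.n_classified}")

    # -- stage 5: the two animal-model fits --------------------------------
    phen_common = phenotypes[phenotypes["id"].map(str).isin(common)]
    trait_mean = float(phen_common["value"].mean())
    mcmc = dict(fixed_effects=("measurer",), include_year=config.include_year,
                n_iter=config.n_iter, n_burnin=config.n_burnin,
                n_chains=config.n_chains, thin=config.thin)
    draws_p = fit_animal_model(phen_common,
                               ModelSpec(relatedness=A, seed=config.seed + 21, **mcmc))
    draws_g = fit_animal_model(phen_common,
                               ModelSpec(relatedness=G, seed=config.seed + 22, **mcmc))
    save("draws_P.csv", lambda p: draws_p.draws.to_csv(p, index=False))
    save("draws_G.csv", lambda p: draws_g.draws.to_csv(p, index=False))
    log_lines.append(f"stage\tfits\tn_obs={draws_p.n_obs}\tn_ind={draws_p.n_individuals}")

    # -- stage 6: report ---------------------------------------------------
    cols = {"P": _column_summaries(draws_p, trait_mean),
            "G": _column_summaries(draws_g, trait_mean)}
    table1 = format_table1(cols)
    h2p = summarize_heritability(draws_p)
    h2g = summarize_heritability(draws_g)
    gcp = genetic_coefficient(draws_p, trait_mean)
    gcg = genetic_coefficient(draws_g, trait_mean)

    def comp(draws, name):
        v = draws.draws[name].to_numpy()
        lo, hi = np.percentile(v, [2.5, 97.5])
        return (float(v.mean()), float(lo), float(hi))

    va_p, va_g = comp(draws_p, "Va"), comp(draws_g, "Va")
    vpe_p, vpe_g = comp(draws_p, "Vpe"), comp(draws_g, "Vpe")
    n_pair = min(len(draws_p.draws), len(draws_g.draws))
    prob = float(np.mean(draws_g.draws["Va"].to_numpy()[:n_pair]
                         > draws_p.draws["Va"].to_numpy()[:n_pair]))
    report = ComparisonReport(
        table1=table1,
        p_summary=summarize_model(draws_p),
        g_summary=summarize_model(draws_g),
        h2_p=(h2p.mean, h2p.lower, h2p.upper),
        h2_g=(h2g.mean, h2g.lower, h2g.upper),
        gc_p=(gcp.mean, gcp.lower, gcp.upper),
        gc_g=(gcg.mean, gcg.lower, gcg.upper),
        va_p=va_p, va_g=va_g, vpe_p=vpe_p, vpe_g=vpe_g,
        mantel=mantel,
        paternity_counts={"n_epp": paternity.n_epp,
                          "n_within_pair": paternity.n_within_pair,
                          "n_unresolved": paternity.n_unresolved,
                          "n_pairs": len(paternity.assignments),
                          "epp_rate_percent": paternity.epp_rate_percent},
        pedigree_before=dataclasses.asdict(summary_full),
        pedigree_after=dataclasses.asdict(summary_trim),
        qc_attrition=qc.attrition,
        h2_cri_overlap=_overlap(h2p.lower, h2p.upper, h2g.lower, h2g.upper),
        va_cri_overlap=_overlap(va_p[1], va_p[2], va_g[1], va_g[2]),
        prob_va_g_gt_p=prob,
        trait_mean=trait_mean,
        n_obs=draws_p.n_obs,
        n_individuals=draws_p.n_individuals,
        artifacts=artifacts,
    )
    save("report.txt", lambda p: p.write_text(table1 + "\n"))
    save("report.json", lambda p: p.write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
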