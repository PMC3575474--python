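"""File formats, run configuration and the pipeline driver.

Formats: PLINK text ped/map (1-based, centiMorgan map positions, "0 0" for
missing genotypes), tab-separated AIM-panel and results tables, flat YAML
run configuration.  Internally coordinates are 0-based and genetic
distances are Morgans.  Every pipeline run re-serialises its resolved
configuration next to its outputs so artifacts are reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import SnpCounts, allelic_test, logistic_adjusted, qc_filter
from .hmm import estimate_global_admixture, forward_backward, mean_local_ancestry
from .panel import AimPanel, build_aim_panel
from .riskmetrics import par_joint, par_single, reorient_to_risk
from .scan import RiskModel, run_case_only_scan
from .simulate import Cohort, DiseaseModel, ascertain_cases

logger = logging.getLogger("admixscan")


class DataFormatError(ValueError):
    pass


# --- PLINK text ped/map ---------------------------------------------------

def write_ped_map(
    cohort: Cohort, panel: AimPanel, prefix, force: bool = False
) -> tuple[Path, Path]:
    """Write a cohort as PLINK text ped/map.

    The counted (reference) allele is written as 'G', the other as 'A';
    missing genotypes as "0 0".  Phenotype column: 2 = case, 1 = control.
    """
    ped_path, map_path = Path(f"{prefix}.ped"), Path(f"{prefix}.map")
    for p in (ped_path, map_path):
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; pass force=True to overwrite")
    with open(map_path, "w") as fh:
        for row in panel.table.itertuples():
            fh.write(f"{row.chrom}\t{row.marker_id}\t"
                     f"{row.genetic_pos_M * 100:.6f}\t{row.phys_pos_bp}\n")
    code = {0: "A A", 1: "G A", 2: "G G", -1: "0 0"}
    with open(ped_path, "w") as fh:
        for i in range(cohort.n_individuals):
            pheno = 2 if cohort.phenotype[i] else 1
            fields = [f"F{i + 1}", f"I{i + 1}", "0", "0", "0", str(pheno)]
            fields += [code[int(g)] for g in cohort.genotypes[i]]
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(
    ped_path, map_path, counted_allele: str | dict = "G"
) -> tuple[Cohort, AimPanel]:
    """Read PLINK text ped/map into a cohort and marker metadata.

    Genotypes are recoded to the dosage of the counted allele ("G" by
    default, or a {marker_id: allele} mapping); "0 0" becomes missing.  A
    marker showing more than two allele symbols is a data error.

    The returned panel carries NaN ancestral frequencies (the map file has
    none); the cohort's ``M`` is NaN until estimated.
    """
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                raise DataFormatError(f"bad map line: {line!r}")
            map_rows.append((int(parts[0]), parts[1],
                             float(parts[2]) / 100.0, int(parts[3])))
    m = len(map_rows)

    rows, phenos = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise DataFormatError(
                    f"ped line {ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            phenos.append(parts[5] == "2")
            rows.append(parts[6:])
    n = len(rows)
    genotypes = np.full((n, m), -1, dtype=np.int8)
    for j in range(m):
        marker = map_rows[j][1]
        counted = (counted_allele.get(marker, "G")
                   if isinstance(counted_allele, dict) else counted_allele)
        seen = set()
        for i in range(n):
            a1, a2 = rows[i][2 * j], rows[i][2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            seen.update((a1, a2))
            genotypes[i, j] = (a1 == counted) + (a2 == counted)
        if len(seen - {counted}) > 1:
            raise DataFormatError(
                f"marker {marker} has more than two alleles: {sorted(seen)}"
            )
    panel_table = pd.DataFrame(
        map_rows, columns=["chrom", "marker_id", "genetic_pos_M", "phys_pos_bp"]
    )
    panel_table["freq_pop1"] = np.nan
    panel_table["freq_pop2"] = np.nan
    panel = AimPanel(panel_table[["marker_id", "chrom", "genetic_pos_M",
                                  "phys_pos_bp", "freq_pop1", "freq_pop2"]])
    cohort = Cohort(genotypes=genotypes, phenotype=np.array(phenos, bool),
                    M=np.full(n, np.nan), panel=panel)
    return cohort, panel


# --- result tables --------------------------------------------------------

def _check_path(path, force: bool) -> Path:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_scan_results(result, panel: AimPanel, path, force: bool = False) -> Path:
    """Per-marker scan table: weighted LOD and (when present) Z, sorted by
    (chrom, position)."""
    path = _check_path(path, force)
    tab = panel.table[["marker_id", "chrom", "genetic_pos_M", "phys_pos_bp"]].copy()
    tab["weighted_lod"] = result.weighted
    tab["z"] = result.z if result.z is not None else np.nan
    tab["z_p"] = result.z_pvalue if result.z_pvalue is not None else np.nan
    tab = tab.sort_values(["chrom", "phys_pos_bp"], kind="stable")
    with open(path, "w") as fh:
        fh.write("\t".join(tab.columns) + "\n")
        for row in tab.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return path


def write_assoc_results(table: pd.DataFrame, path, force: bool = False) -> Path:
    """Association results TSV with 6-significant-digit floats and NA for
    missing values."""
    path = _check_path(path, force)
    with open(path, "w") as fh:
        fh.write("\t".join(table.columns) + "\n")
        for row in table.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return path


# --- configuration and pipeline ------------------------------------------

@dataclass
class RunConfig:
    """Flat, YAML-serialisable description of one pipeline run."""

    seed: int = 0
    out_prefix: str = "admixscan_run"
    # simulation
    n_markers: int = 200
    n_cases: int = 500
    n_controls: int = 200
    psi_true: float = 1.5
    baseline: float = 0.05
    causal_marker: str | None = "auto"
    generations: float = 6.0
    admixture_mean: float = 0.175
    admixture_sd: float = 0.09
    sigma_target: float = 0.56
    min_sigma: float = 0.30
    # scan
    run_scan: bool = True
    psi_min: float = 0.4
    psi_max: float = 3.0
    psi_n: int = 27
    weight_mode: str = "bayes_average"
    use_true_admixture: bool = False
    # association QC
    run_assoc: bool = True
    miss_snp: float = 0.10
    miss_ind: float = 0.05
    hwe_p: float = 0.001
    maf: float = 0.01

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def pipeline_run(config: RunConfig, force: bool = False) -> dict:
    """simulate -> ancestry -> scan -> assoc -> metrics, writing artifacts.

    Outputs land under ``config.out_prefix`` with fixed names; a JSON
    summary (seed, stage wall times, headline numbers) is returned and
    written alongside.
    """
    t_all = time.time()
    out = Path(config.out_prefix)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed, "stages": {}}
    rng = np.random.default_rng(config.seed)

    # simulate
    t0 = time.time()
    panel = build_aim_panel(config.n_markers, sigma_target=config.sigma_target,
                            min_sigma=config.min_sigma,
                            seed=rng.integers(2 ** 31))
    causal = config.causal_marker
    if causal == "auto":
        causal = panel.table["marker_id"].iloc[panel.n_markers // 2]
    model = DiseaseModel(causal_marker=causal if config.psi_true != 1 else None,
                         psi=config.psi_true, baseline=config.baseline)
    cohort = ascertain_cases(
        panel, model, config.n_cases, config.n_controls,
        T=config.generations, admixture_mean=config.admixture_mean,
        admixture_sd=config.admixture_sd, seed=rng.integers(2 ** 31),
    )
    panel.to_tsv(out / "panel.tsv")
    write_ped_map(cohort, panel, out / "cohort", force=True)
    pd.DataFrame(cohort.genotypes,
                 columns=panel.table["marker_id"]).to_csv(
        out / "dosage.tsv", sep="\t", index=False)
    if cohort.tracts is not None:
        np.savetxt(out / "truth_tracts.tsv",
                   cohort.tracts.reshape(cohort.n_individuals, -1),
                   fmt="%d", delimiter="\t")
    summary["stages"]["simulate"] = round(time.time() - t0, 3)
    logger.info("simulated %d cases / %d controls at %d markers",
                config.n_cases, config.n_controls, panel.n_markers)

    # ancestry
    t0 = time.time()
    m_hat = estimate_global_admixture(panel, cohort.genotypes)
    M_used = cohort.M if config.use_true_admixture else m_hat
    post = forward_backward(panel, cohort.genotypes, M_used,
                            T=config.generations)
    mean_anc = mean_local_ancestry(post, cohort.cases)
    pd.DataFrame({"individual": np.arange(cohort.n_individuals),
                  "m_hat": m_hat, "m_true": cohort.M,
                  "case": cohort.phenotype.astype(int)}).to_csv(
        out / "admixture.tsv", sep="\t", index=False)
    summary["stages"]["ancestry"] = round(time.time() - t0, 3)
    summary["mean_M_hat"] = float(np.mean(m_hat))

    scan_res = None
    if config.run_scan:
        t0 = time.time()
        risk = RiskModel.default(lo=config.psi_min, hi=config.psi_max,
                                 n=config.psi_n)
        case_idx, ctrl_idx = cohort.cases, cohort.controls
        scan_res = run_case_only_scan(
            panel, cohort.genotypes[case_idx], np.asarray(M_used)[case_idx],
            model=risk, T=config.generations, mode=config.weight_mode,
            control_genotypes=(cohort.genotypes[ctrl_idx]
                               if len(ctrl_idx) else None),
            control_M=np.asarray(M_used)[ctrl_idx] if len(ctrl_idx) else None,
        )
        write_scan_results(scan_res, panel, out / "scan.tsv", force=True)
        summary["stages"]["scan"] = round(time.time() - t0, 3)
        summary["best_marker"] = scan_res.best_marker
        summary["best_lod"] = round(scan_res.best_lod, 4)
        summary["genome_score"] = round(scan_res.genome, 4)

    if config.run_assoc:
        t0 = time.time()
        g_qc, ind_idx, snp_idx, qc_report = qc_filter(
            cohort.genotypes, cohort.phenotype, miss_snp=config.miss_snp,
            miss_ind=config.miss_ind, hwe_p=config.hwe_p, maf=config.maf,
            marker_ids=panel.table["marker_id"].to_numpy(),
        )
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        phe = cohort.phenotype[ind_idx]
        cov = np.asarray(M_used)[ind_idx]
        rows = []
        for k, j in enumerate(snp_idx):
            counts = SnpCounts.from_dosage(g_qc[:, k], phe)
            res = allelic_test(counts)
            adj_p = np.nan
            if "monomorphic" not in res.flags and len(np.unique(phe)) == 2:
                try:
                    adj_p = logistic_adjusted(g_qc[:, k], phe, cov)["p_value"]
                except Exception:
                    pass
            rows.append((panel.table["marker_id"].iloc[j], res.freq_case,
                         res.freq_control, res.odds_ratio, res.ci_low,
                         res.ci_high, res.p_value, adj_p))
        assoc_tab = pd.DataFrame(rows, columns=[
            "marker_id", "freq_case", "freq_control", "odds_ratio",
            "ci_low", "ci_high", "p_allelic", "p_adjusted"])
        write_assoc_results(assoc_tab, out / "assoc.tsv", force=True)
        summary["stages"]["assoc"] = round(time.time() - t0, 3)
        summary["n_snps_post_qc"] = int(len(snp_idx))

        # metrics on the strongest association, oriented to the risk allele
        valid = assoc_tab.dropna(subset=["odds_ratio"])
        if len(valid):
            top = valid.sort_values("p_allelic").iloc[0]
            p_risk, or_risk = reorient_to_risk(top.freq_control, top.odds_ratio)
            summary["top_assoc_marker"] = str(top.marker_id)
            summary["top_assoc_par_pct"] = round(
                100 * par_single(p_risk, or_risk), 2)

    summary["wall_time"] = round(time.time() - t_all, 3)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
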