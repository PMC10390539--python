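"""Canned benchmark experiments.

These functions wire the generator, the imputer and the metrics into the
study designs the package exists for, with fixed desk-scale conditions:

* ``matched_vs_mismatched_experiment`` — the central comparison: impute
  one population's targets from its own reference panel and from an
  equally sized panel of a diverged population, and score both.
* ``calibration_experiment`` — how well the per-variant estimated R^2
  tracks realised dosage accuracy, summarised as pooled r^2 per
  estimated-R^2 decile.
* ``admixture_recovery_experiment`` — K=2 EM ancestry estimates against
  the generator's true per-haplotype ancestry.
* ``mds_separation_experiment`` — first MDS axis versus subpopulation
  labels on LD-pruned markers.

Every experiment is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import concordance as conc
from . import popstruct as ps
from .lsimpute import LSParams, impute_cohort
from .simdata import SimConfig, simulate_cohort

__all__ = [
    "PANEL_EXPERIMENT_CONFIG",
    "CALIBRATION_CONFIG",
    "ADMIXTURE_CONFIG",
    "matched_vs_mismatched_experiment",
    "calibration_experiment",
    "admixture_recovery_experiment",
    "mds_separation_experiment",
]

# Two populations symmetrically drifted at F = 0.05 from a shared
# ancestor; 25 diploid targets from population A; equally sized panels.
PANEL_EXPERIMENT_CONFIG = SimConfig(
    n_sites=3000, n_ancestral_haps=100, panel_size=150, pop_sizes=(25, 25),
    fst_per_pop=(0.05, 0.05), recomb_rate=2e-6, flip_rate=1e-3,
    array_maf_min=0.05, array_spacing=2)

# A larger cohort with a panel only modestly larger than the founder
# pool, so imputation quality genuinely varies across variants.
CALIBRATION_CONFIG = SimConfig(
    n_sites=2000, n_ancestral_haps=200, panel_size=150, pop_sizes=(200,),
    fst_per_pop=(0.05,), recomb_rate=2e-6, flip_rate=1e-3,
    array_maf_min=0.05, array_spacing=2)

# Two populations at F = 0.1 plus admixed individuals, 100 samples total.
ADMIXTURE_CONFIG = SimConfig(
    n_sites=2000, n_ancestral_haps=100, panel_size=50, pop_sizes=(40, 40),
    fst_per_pop=(0.1, 0.1), admixed_fraction=0.25, admix_q=0.5,
    recomb_rate=2e-6, flip_rate=1e-3)


def _params_for(cfg: SimConfig) -> LSParams:
    # switch intensity calibrated to the generative recombination rate
    return LSParams(rho=cfg.recomb_rate * 2 * cfg.panel_size, err=0.01)


def matched_vs_mismatched_experiment(seed: int, n_replicates: int = 20,
                                     cfg: SimConfig = PANEL_EXPERIMENT_CONFIG
                                     ) -> pd.DataFrame:
    """Impute pop-A targets from the matched (A) and mismatched (B) panel.

    Per replicate: cohort medians of per-sample GCR for both panels,
    the mismatched panel's pooled r^2 in the common/low-frequency/rare
    AF bins, and the cohort median GCR restricted to high-confidence
    (estimated R^2 >= 0.8) variants for both panels.  Evaluation covers
    every simulated site (the truth-set intersection), typed and
    untyped.
    """
    params = _params_for(cfg)
    n_a = cfg.pop_sizes[0]
    rows = []
    for rep in range(n_replicates):
        cohort = simulate_cohort(cfg.with_(seed=seed + rep))
        targets = cohort.targets[: 2 * n_a]
        truth = cohort.truth_genotypes()[:n_a]
        sample_ids = cohort.sample_ids[:n_a]
        eval_idx = np.arange(cfg.n_sites)
        row = {"replicate": rep}
        for tag, pop in (("matched", "A"), ("mismatched", "B")):
            ds = impute_cohort(targets, cohort.typed_idx, cohort.panels[pop],
                               params, sample_ids=sample_ids)
            gcr = conc.gcr_per_sample(ds.hard_calls, truth, sample_ids,
                                      eval_idx)
            row[f"{tag}_median_gcr"] = float(gcr.median())
            strat = conc.gcr_by_stratum(ds, truth, eval_idx)
            row[f"{tag}_highconf_median_gcr"] = float(
                strat.iloc[:, -1].median())
            if tag == "mismatched":
                r2b = conc.pooled_r2_by_bin(ds.dosages, truth,
                                            cohort.ancestral_freqs,
                                            conc.COARSE_BINS, eval_idx)
                row["r2_common"] = float(r2b.iloc[0])
                row["r2_low_frequency"] = float(r2b.iloc[1])
                row["r2_rare"] = float(r2b.iloc[2])
        rows.append(row)
    return pd.DataFrame(rows).set_index("replicate")


@dataclass
class CalibrationResult:
    decile_table: pd.DataFrame  # est-R2 decile -> mean est R2, pooled true r2
    spearman: float


def calibration_experiment(seed: int,
                           cfg: SimConfig = CALIBRATION_CONFIG
                           ) -> CalibrationResult:
    """Pooled dosage-truth r^2 within each estimated-R^2 decile.

    Deciles are quantile bins of the per-variant estimated R^2; within
    each, all (sample, variant) dosage/truth pairs are pooled into one
    squared correlation.  Deciles with undefined r^2 (no dosage
    variance) are dropped from the Spearman rank correlation between
    decile index and pooled r^2.
    """
    cohort = simulate_cohort(cfg.with_(seed=seed))
    ds = impute_cohort(cohort.targets, cohort.typed_idx, cohort.panels["A"],
                       _params_for(cfg), sample_ids=cohort.sample_ids)
    truth = cohort.truth_genotypes().astype(float)
    r2 = ds.est_r2
    edges = np.quantile(r2, np.linspace(0.0, 1.0, 11))
    decile = np.clip(np.searchsorted(edges[1:-1], r2, side="right"), 0, 9)
    rows = []
    for d in range(10):
        cols = decile == d
        x = ds.dosages[:, cols].ravel()
        y = truth[:, cols].ravel()
        pooled = (float(np.corrcoef(x, y)[0, 1] ** 2)
                  if cols.any() and x.std() > 0 and y.std() > 0 else np.nan)
        rows.append({"decile": d, "n_variants": int(cols.sum()),
                     "mean_est_r2": float(r2[cols].mean()) if cols.any() else np.nan,
                     "pooled_true_r2": pooled})
    table = pd.DataFrame(rows).set_index("decile")
    ok = table["pooled_true_r2"].notna()
    rho = float(spearmanr(table.index[ok],
                          table.loc[ok, "pooled_true_r2"]).statistic)
    return CalibrationResult(table, rho)


def admixture_recovery_experiment(seed: int,
                                  cfg: SimConfig = ADMIXTURE_CONFIG
                                  ) -> dict:
    """Fit K=2 admixture to a simulated admixed cohort; score against truth.

    Returns the RMSE between estimated and true per-individual ancestry
    proportions (after label alignment) and whether the EM trace was
    monotone.
    """
    cohort = simulate_cohort(cfg.with_(seed=seed))
    G = cohort.truth_genotypes()
    fit = ps.admixture_em(G, K=2, seed=seed)
    q_hat = ps.align_q_columns(fit.Q, cohort.true_q)
    rmse = float(np.sqrt(np.mean((q_hat - cohort.true_q) ** 2)))
    monotone = bool(np.all(np.diff(fit.loglik_trace) >= -1e-8))
    return {"rmse": rmse, "monotone_loglik": monotone,
            "converged": fit.converged, "n": G.shape[0]}


def mds_separation_experiment(seed: int, n_sites: int = 3000) -> dict:
    """MDS of two fst=0.1 subpopulations on LD-pruned markers.

    Reports whether the two label groups are disjoint on the first MDS
    coordinate (zero overlap of their ranges).
    """
    cfg = SimConfig(seed=seed, n_sites=n_sites, n_ancestral_haps=100,
                    panel_size=50, pop_sizes=(50, 50),
                    fst_per_pop=(0.1, 0.1), recomb_rate=2e-6)
    cohort = simulate_cohort(cfg)
    G = cohort.truth_genotypes()
    kept = ps.ld_prune(G)
    mds = ps.classical_mds(ps.ibs_distance(G[:, kept]), d=2)
    c1 = mds.coordinates[:, 0]
    labels = np.array(cohort.target_pops)
    a, b = c1[labels == "A"], c1[labels == "B"]
    gap = float(max(b.min() - a.max(), a.min() - b.max()))
    return {"separated": gap > 0, "n_markers": int(kept.size), "gap": gap}
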