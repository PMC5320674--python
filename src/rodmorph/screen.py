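"""Morphology vs chemical-genomics correlation statistics.

A chemical-genomics screen assigns each (deletion strain, condition) pair
an S-score: positive when the strain grew more than expected in that
condition, negative when it grew less. Correlating a population morphology
statistic (mean cell width or length) with the S-scores across strains,
condition by condition, identifies chemical sensitivities that track cell
size. Significance uses the exact Student-t distribution of the Pearson
coefficient under the null, with Bonferroni correction over the family of
tested conditions; a 23-class COG (Clusters of Orthologous Groups)
stratification repeats the analysis within gene-function classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

COG_CLASSES = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:23])
STATISTICS = {"width": "width_mean_um", "length": "length_mean_um"}


@dataclass
class CorrelationResult:
    condition: str
    statistic: str                       # "width" or "length"
    n: int
    r: float
    p: float
    significant: bool = False
    stratum: str = "all"
    n_tests: int = 1                     # Bonferroni family size


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson R with a two-sided Student-t p-value.

    Pairs with a missing value in either variable are deleted pairwise.
    Returns (R, p, n). Zero variance in either variable yields NaN (an
    undefined correlation is flagged, never reported as 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd * xd))
    sy = np.sqrt(np.sum(yd * yd))
    if sx == 0 or sy == 0:
        return float("nan"), float("nan"), n
    r = float(np.sum(xd * yd) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, p, n


def correlate_morphology_screen(pop: pd.DataFrame, screen: pd.DataFrame,
                                statistic: str = "width",
                                included_only: bool = True
                                ) -> list[CorrelationResult]:
    """One Pearson correlation per condition between the chosen strain
    morphology statistic and the S-scores, over the strains present in
    both tables (pairwise deletion of missing S-scores)."""
    col = STATISTICS[statistic]
    p = pop.set_index("strain") if "strain" in pop.columns else pop
    if included_only and "included" in p.columns:
        p = p[p["included"]]
    common = p.index.intersection(screen.index)
    if len(common) == 0:
        raise ValueError("no overlap between morphology and screen strains")
    morph = p.loc[common, col].to_numpy(dtype=float)
    results = []
    for cond in screen.columns:
        scores = screen.loc[common, cond].to_numpy(dtype=float)
        ok = np.isfinite(scores) & np.isfinite(morph)
        if ok.sum() < 3:
            continue
        r, pv, n = pearson_with_p(morph[ok], scores[ok])
        results.append(CorrelationResult(condition=str(cond),
                                         statistic=statistic, n=n,
                                         r=r, p=pv))
    return results


def bonferroni_flags(results: list[CorrelationResult],
                     alpha: float = 0.05) -> list[CorrelationResult]:
    """Flag results significant at alpha / n_tested_conditions; the family
    size is recorded in every result."""
    tested = [res for res in results if np.isfinite(res.p)]
    m = max(1, len(tested))
    for res in results:
        res.n_tests = m
        res.significant = bool(np.isfinite(res.p) and res.p <= alpha / m)
    return results


def cog_stratified(pop: pd.DataFrame, screen: pd.DataFrame,
                   cogmap: pd.DataFrame, statistic: str = "width",
                   alpha: float = 0.05, min_strata_n: int = 10,
                   family: str = "classes_x_conditions"
                   ) -> list[CorrelationResult]:
    """Per (COG class, condition) correlations over the strains in that
    class.

    The Bonferroni family defaults to n_classes x n_conditions (every test
    in the stratified run); ``family="conditions"`` corrects per class over
    conditions only. Classes with fewer than ``min_strata_n`` overlapping
    strains are skipped.
    """
    if family not in ("classes_x_conditions", "conditions"):
        raise ValueError("unknown Bonferroni family")
    cmap = (cogmap.set_index("strain")["cog_class"]
            if "strain" in cogmap.columns else cogmap)
    p = pop.set_index("strain") if "strain" in pop.columns else pop
    if "included" in p.columns:
        p = p[p["included"]]
    all_results: list[CorrelationResult] = []
    per_class: dict[str, list[CorrelationResult]] = {}
    for cls in sorted(set(cmap.dropna())):
        strains = cmap.index[cmap == cls]
        sub = p.loc[p.index.intersection(strains)]
        if len(sub.index.intersection(screen.index)) < min_strata_n:
            continue
        try:
            res = correlate_morphology_screen(sub.reset_index(), screen,
                                              statistic,
                                              included_only=False)
        except ValueError:
            continue
        for item in res:
            item.stratum = str(cls)
        per_class[cls] = res
        all_results.extend(res)
    if family == "classes_x_conditions":
        bonferroni_flags(all_results, alpha)
    else:
        for res in per_class.values():
            bonferroni_flags(res, alpha)
    return all_results


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    cols = ["condition", "statistic", "stratum", "n", "r", "p",
            "significant", "n_tests"]
    return pd.DataFrame([{k: getattr(res, k) for k in cols}
                         for res in results], columns=cols)


def synth_screen(n_strains: int = 2465, n_conditions: int = 324,
                 planted: list[tuple[int | str, str, float]] | None = None,
                 noise_sd: float = 1.0, seed: int = 0):
    """Synthetic strain population and S-score table with planted
    morphology-score correlations.

    Strain mean widths are Normal(1.0, 0.08) um; mean lengths couple
    positively to width (1.2 + 2.2 * width + Normal(0, 0.3) um), emulating
    the length-width correlation seen across deletion libraries. Each
    planted tuple (condition, statistic, R_target) makes that condition's
    scores a linear response with population correlation R_target to the
    chosen statistic; all other conditions are pure noise.

    Returns (pop_table, screen_table, ground_truth).
    """
    rng = np.random.default_rng(seed)
    strains = [f"strain_{i:04d}" for i in range(n_strains)]
    widths = rng.normal(1.0, 0.08, n_strains)
    lengths = 1.2 + 2.2 * widths + rng.normal(0.0, 0.3, n_strains)
    pop = pd.DataFrame({"strain": strains,
                        "n_cells": 200,
                        "width_mean_um": widths,
                        "width_sd_um": 0.05,
                        "length_mean_um": lengths,
                        "length_sd_um": 0.3,
                        "width_cv_mean": 0.05,
                        "included": True})
    conditions = [f"cond_{j:03d}" for j in range(n_conditions)]
    scores = rng.normal(0.0, noise_sd, (n_strains, n_conditions))
    truth = {}
    for cond, statistic, r_target in (planted or []):
        j = cond if isinstance(cond, int) else conditions.index(cond)
        stat = widths if statistic == "width" else lengths
        z = (stat - stat.mean()) / stat.std()
        eps = rng.standard_normal(n_strains)
        mix = r_target * z + np.sqrt(max(0.0, 1 - r_target ** 2)) * eps
        scores[:, j] = noise_sd * mix
        truth[conditions[j]] = {"statistic": statistic, "r": r_target}
    screen_table = pd.DataFrame(scores, index=pd.Index(strains, name="strain"),
                                columns=conditions)
    return pop, screen_table, truth
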