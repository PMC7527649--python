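"""Nonparametric statistical pipeline for conformity data.

Operates on the trial-level interchange schema (see
:mod:`confbayes.simulate`) and mirrors a standard behavioral workflow:

* trial-level conformity coding: a trial counts as conformity iff the
  second response equals the peer-majority response — on congruent
  trials *staying* is conformity and shifting away is non-conformity;
* subject-level summaries first (proportions and mean RTs per subject),
  then group means with between-subject standard errors — group tests
  never pool trials, avoiding pseudo-replication;
* a nonparametric battery: Shapiro-Wilk normality report, one-sample and
  paired Wilcoxon signed-rank tests, Mann-Whitney pairwise group
  contrasts with Benjamini-Hochberg FDR within declared families,
  Kruskal-Wallis across groups, a Friedman omnibus across the four NPI
  levels, and a chi-square test on the believes-worse proportions;
* model-vs-data comparison: observed conformity per incongruent NPI
  level against the equal-weight (BNE) posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bayes import bne_posterior
from .simulate import GROUPS, npi_to_nm

__all__ = [
    "TestResult",
    "code_conformity",
    "subject_summaries",
    "summarize",
    "run_test_battery",
    "compare_to_bne",
]

NPI_LEVELS = (-3, -1, 1, 3)


@dataclass
class TestResult:
    """One statistical test outcome.

    ``p_adjusted`` is filled only for tests belonging to an FDR family
    (Benjamini-Hochberg step-up within ``family_id``).  Tests that could
    not run (insufficient n, zero variance) carry ``skipped=True`` and a
    reason in ``note`` — they are reported, never silently dropped.
    """

    test_name: str
    statistic: float = float("nan")
    df: Optional[float] = None
    p_raw: float = float("nan")
    p_adjusted: Optional[float] = None
    family_id: Optional[str] = None
    n: int = 0
    skipped: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def code_conformity(row) -> int:
    """Trial-level conformity: 1 iff the second response matches the peer majority.

    Accepts a mapping with ``second_response`` and ``peer1..peer3``.  Note
    the asymmetry with shifting: on congruent trials no-shift is coded as
    conformity and a shift away from the majority as non-conformity.
    """
    peers = [row["peer1"], row["peer2"], row["peer3"]]
    counts = pd.Series(peers).value_counts()
    majority = counts.idxmax()
    if counts.max() < 2:  # cannot happen with 3 binary peers; defensive
        raise ValueError("no strict peer majority")
    return int(row["second_response"] == majority)


def _rate(mask_num: pd.Series, mask_den: pd.Series) -> float:
    d = int(mask_den.sum())
    return float(mask_num[mask_den].mean()) if d else float("nan")


def subject_summaries(data: pd.DataFrame) -> pd.DataFrame:
    """Per-subject proportions and RT means (one row per subject).

    Rates are computed only over trials where the conditioning event
    occurred; empty cells are NaN and carry a zero count in the matching
    ``n_*`` column.
    """
    if data.empty:
        raise ValueError("empty dataset")
    rows = []
    for (sid, group), d in data.groupby(["subject_id", "group"], sort=True):
        incong = d["npi"] < 0
        cong = d["npi"] > 0
        row = {
            "subject_id": sid,
            "group": group,
            "actual_accuracy": float(d["first_correct"].mean()),
            "conform_rate_incongruent": _rate(d["conformed"], incong),
            "conform_rate_congruent": _rate(d["conformed"], cong),
            "n_incongruent": int(incong.sum()),
            "n_congruent": int(cong.sum()),
            "mean_rt_incongruent": float(d.loc[incong, "rt_second"].mean()) if incong.any() else float("nan"),
            "mean_rt_congruent": float(d.loc[cong, "rt_second"].mean()) if cong.any() else float("nan"),
            "mean_rt": float(d["rt_second"].mean()),
            "follow_right_rate": _rate(d["conformed"], d["majority_correct"] == 1),
            "follow_wrong_rate": _rate(d["conformed"], d["majority_correct"] == 0),
        }
        for level in NPI_LEVELS:
            mask = d["npi"] == level
            row[f"conform_npi_{level}"] = _rate(d["conformed"], mask)
            row[f"n_npi_{level}"] = int(mask.sum())
        if "believes_worse" in d.columns:
            row["believes_worse"] = int(d["believes_worse"].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_se(x: pd.Series) -> tuple:
    x = x.dropna()
    n = len(x)
    if n == 0:
        return float("nan"), float("nan"), 0
    se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(x.mean()), se, n


def summarize(data: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Group-level mean (SE) tables of conformity by NPI/condition plus RTs.

    Returns ``{"by_npi": ..., "by_condition": ..., "rt": ..., "subjects": ...}``;
    the first two mirror the study's NPI-by-group and condition summary
    layouts.  Means and SEs are over subjects (between-subject SE).
    """
    subj = subject_summaries(data)
    groups = [g for g in GROUPS if g in set(subj["group"])] or sorted(set(subj["group"]))

    by_npi = []
    for level in NPI_LEVELS:
        row: dict = {"npi": level}
        for g in groups:
            m, se, n = _mean_se(subj.loc[subj["group"] == g, f"conform_npi_{level}"])
            row[f"{g}_mean"], row[f"{g}_se"], row[f"{g}_n"] = m, se, n
        by_npi.append(row)

    by_condition = []
    for label, col in (
        ("incongruent", "conform_rate_incongruent"),
        ("congruent", "conform_rate_congruent"),
    ):
        row = {"condition": label}
        for g in groups:
            m, se, n = _mean_se(subj.loc[subj["group"] == g, col])
            row[f"{g}_mean"], row[f"{g}_se"], row[f"{g}_n"] = m, se, n
        by_condition.append(row)

    rt = []
    for label, col in (
        ("overall", "mean_rt"),
        ("congruent", "mean_rt_congruent"),
        ("incongruent", "mean_rt_incongruent"),
    ):
        row = {"rt": label}
        for g in groups:
            m, se, n = _mean_se(subj.loc[subj["group"] == g, col])
            row[f"{g}_mean"], row[f"{g}_se"], row[f"{g}_n"] = m, se, n
        rt.append(row)

    return {
        "by_npi": pd.DataFrame(by_npi),
        "by_condition": pd.DataFrame(by_condition),
        "rt": pd.DataFrame(rt),
        "subjects": subj,
    }


def _wilcoxon_one_sample(x: np.ndarray, mu: float = 0.0) -> tuple:
    """Wilcoxon signed-rank vs a constant; zero-differences discarded
    (Wilcoxon's method), exact distribution for n <= 25."""
    d = np.asarray(x, dtype=float) - mu
    d = d[~np.isnan(d)]
    nz = d[d != 0]
    if len(nz) == 0:
        return float("nan"), float("nan"), len(d), "all differences zero"
    method = "exact" if len(nz) <= 25 else "approx"
    try:
        res = stats.wilcoxon(nz, zero_method="wilcox", method=method)
    except ValueError as e:  # e.g. exact method with ties falls back
        res = stats.wilcoxon(nz, zero_method="wilcox", method="approx")
        return float(res.statistic), float(res.pvalue), len(d), str(e)
    return float(res.statistic), float(res.pvalue), len(d), ""


def _paired(test_name: str, a: pd.Series, b: pd.Series, family: Optional[str] = None) -> TestResult:
    mask = a.notna() & b.notna()
    stat, p, n, note = _wilcoxon_one_sample(a[mask].to_numpy() - b[mask].to_numpy())
    skipped = np.isnan(p)
    return TestResult(
        test_name=test_name, statistic=stat, p_raw=p, family_id=family,
        n=int(mask.sum()), skipped=bool(skipped), note=note,
    )


def _apply_fdr(results: List[TestResult]) -> None:
    """Benjamini-Hochberg step-up within each declared family, in place."""
    families: Dict[str, List[TestResult]] = {}
    for r in results:
        if r.family_id and not r.skipped and not np.isnan(r.p_raw):
            families.setdefault(r.family_id, []).append(r)
    for members in families.values():
        p = [r.p_raw for r in members]
        adj = multipletests(p, method="fdr_bh")[1]
        for r, q in zip(members, adj):
            r.p_adjusted = float(q)


def run_test_battery(data: pd.DataFrame, alpha: float = 0.05) -> List[TestResult]:
    """Run the full nonparametric battery on subject-level summaries.

    All tests operate on subject-level proportions or subject RT means.
    Families for FDR adjustment: the three pairwise group contrasts on
    incongruent conformity, on NPI=-3 conformity, and on mean RT.
    """
    subj = subject_summaries(data)
    groups = [g for g in GROUPS if g in set(subj["group"])]
    results: List[TestResult] = []

    # (a) normality gate, reported but not branching
    for g in groups:
        x = subj.loc[subj["group"] == g, "conform_rate_incongruent"].dropna()
        if len(x) >= 3 and x.nunique() > 1:
            w, p = stats.shapiro(x)
            results.append(TestResult(f"shapiro_incongruent_{g}", float(w), None, float(p), n=len(x)))
        else:
            results.append(TestResult(
                f"shapiro_incongruent_{g}", skipped=True, n=len(x),
                note="needs >= 3 distinct subject values",
            ))

    # (b) conformity different from zero, per group
    for g in groups:
        x = subj.loc[subj["group"] == g, "conform_rate_incongruent"].dropna().to_numpy()
        stat, p, n, note = _wilcoxon_one_sample(x, 0.0)
        results.append(TestResult(
            f"wilcoxon_conformity_vs_zero_{g}", stat, None, p, n=n,
            skipped=bool(np.isnan(p)), note=note,
        ))

    # (c) congruent vs incongruent conformity, pooled subjects
    results.append(_paired(
        "wilcoxon_congruent_vs_incongruent",
        subj["conform_rate_congruent"], subj["conform_rate_incongruent"],
    ))

    # (d) Kruskal-Wallis across groups
    for label, col in (
        ("incongruent_conformity", "conform_rate_incongruent"),
        ("mean_rt", "mean_rt"),
        ("accuracy", "actual_accuracy"),
    ):
        samples = [
            subj.loc[subj["group"] == g, col].dropna().to_numpy() for g in groups
        ]
        pooled = np.concatenate(samples) if samples else np.array([])
        if len(samples) >= 2 and all(len(s) >= 2 for s in samples) and len(np.unique(pooled)) > 1:
            h, p = stats.kruskal(*samples)
            results.append(TestResult(
                f"kruskal_{label}", float(h), float(len(samples) - 1), float(p),
                n=int(sum(len(s) for s in samples)),
            ))
        else:
            note = ("all values identical" if len(np.unique(pooled)) <= 1
                    else "needs >= 2 subjects per group")
            results.append(TestResult(f"kruskal_{label}", skipped=True, note=note))

    # (e) within-subject omnibus over the four NPI levels (Friedman)
    cols = [f"conform_npi_{k}" for k in NPI_LEVELS]
    complete = subj.dropna(subset=cols)
    n_dropped = len(subj) - len(complete)
    if len(complete) >= 3 and complete[cols].to_numpy().std() > 0:
        chi2, p = stats.friedmanchisquare(*[complete[c].to_numpy() for c in cols])
        results.append(TestResult(
            "friedman_npi_levels", float(chi2), float(len(cols) - 1), float(p),
            n=len(complete),
            note=f"{n_dropped} subjects without all four NPI levels excluded" if n_dropped else "",
        ))
    else:
        results.append(TestResult(
            "friedman_npi_levels", skipped=True, n=len(complete),
            note="needs >= 3 subjects with all four NPI levels and non-constant rates",
        ))

    # (f) pairwise group contrasts, BH within each family
    fam_cols = (
        ("pairwise_incongruent", "conform_rate_incongruent"),
        ("pairwise_npi_-3", "conform_npi_-3"),
        ("pairwise_rt", "mean_rt"),
    )
    for family, col in fam_cols:
        for g1, g2 in combinations(groups, 2):
            a = subj.loc[subj["group"] == g1, col].dropna().to_numpy()
            b = subj.loc[subj["group"] == g2, col].dropna().to_numpy()
            name = f"mannwhitney_{col}_{g1}_vs_{g2}"
            if len(a) >= 2 and len(b) >= 2:
                u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                results.append(TestResult(
                    name, float(u), None, float(p), family_id=family, n=len(a) + len(b),
                ))
            else:
                results.append(TestResult(
                    name, family_id=family, skipped=True,
                    note="needs >= 2 subjects per group", n=len(a) + len(b),
                ))

    # (g) follow-right vs follow-wrong
    results.append(_paired(
        "wilcoxon_follow_right_vs_wrong",
        subj["follow_right_rate"], subj["follow_wrong_rate"],
    ))

    # (h) RT congruent vs incongruent, per group and pooled
    results.append(_paired(
        "wilcoxon_rt_incongruent_vs_congruent",
        subj["mean_rt_incongruent"], subj["mean_rt_congruent"],
    ))
    for g in groups:
        gs = subj[subj["group"] == g]
        results.append(_paired(
            f"wilcoxon_rt_incongruent_vs_congruent_{g}",
            gs["mean_rt_incongruent"], gs["mean_rt_congruent"],
        ))

    # (i) believes-worse proportions across groups (2 x k table)
    if "believes_worse" in subj.columns:
        table = pd.crosstab(subj["believes_worse"], subj["group"])
        if table.shape[0] == 2 and (table.to_numpy().sum(axis=0) > 0).all():
            chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy())
            results.append(TestResult(
                "chi2_believes_worse", float(chi2), float(dof), float(p), n=len(subj),
            ))
        else:
            results.append(TestResult(
                "chi2_believes_worse", skipped=True, n=len(subj),
                note="believes_worse constant; contingency table degenerate",
            ))

    _apply_fdr(results)
    return results


def compare_to_bne(data: pd.DataFrame, p_c: float = 0.5524) -> pd.DataFrame:
    """Observed conformity vs the equal-weight posterior, per group and NPI.

    For each incongruent NPI level and group: observed subject-mean
    conformity, the BNE posterior under the NPI -> (n, m) map, and a
    one-sample Wilcoxon of subject proportions against that constant.
    """
    subj = subject_summaries(data)
    groups = [g for g in GROUPS if g in set(subj["group"])] or sorted(set(subj["group"]))
    rows = []
    for level in (-3, -1):
        n_agree, m_disagree = npi_to_nm(level)
        bne = bne_posterior(p_c, n_agree, m_disagree)
        for g in groups:
            x = subj.loc[subj["group"] == g, f"conform_npi_{level}"].dropna().to_numpy()
            mean, se, n = _mean_se(pd.Series(x))
            stat, p, _, note = _wilcoxon_one_sample(x, bne)
            rows.append({
                "npi": level, "group": g, "observed_mean": mean, "observed_se": se,
                "bne": bne, "n": n, "wilcoxon_statistic": stat, "p_vs_bne": p,
                "note": note,
            })
    return pd.DataFrame(rows)
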