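"""Group comparisons of background-error profiles.

All tests are two-sample Welch (unequal-variance) t-tests on per-sample
rates, the robust default when group variances differ.  Class-wise
comparisons are Bonferroni-corrected across the simultaneous class tests
(12 directional or 6 collapsed); the total rate is tested separately and
uncorrected.  Per-position tests are corrected within each reference-base
family (all tests at A-reference positions together, etc.), since the
position counts per family are reported separately and the families probe
different sequence contexts.

Zero-variance degeneracies are resolved deterministically rather than left
as NaN: if both groups are constant and equal the position is uninformative
(p = 1); constant but different values are flagged with a p = 0 sentinel and
counted, so downstream consumers can audit them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ALL_CLASSES, BASES, COLLAPSED_CLASSES, ErrorProfile, FragmentBinProfile
from .profiling import FilterConfig, MaskSet, compute_error_profile


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t and two-sided p with the zero-variance conventions.

    ``a`` and ``b`` are 2-D (rows x samples).  Rows where both groups have
    zero variance get p = 1 if the means agree, else the p = 0 sentinel.
    """
    import warnings

    with warnings.catch_warnings():
        # near-identical rows trigger scipy's catastrophic-cancellation
        # warning; those rows are handled by the zero-variance rules below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    same = degenerate & (a.mean(axis=1) == b.mean(axis=1))
    diff = degenerate & ~same
    p[same] = 1.0
    t[same] = 0.0
    p[diff] = 0.0
    t[diff] = np.where(a.mean(axis=1)[diff] > b.mean(axis=1)[diff], np.inf, -np.inf)
    return t, p


def _two_groups(profiles_by_group: Mapping[str, Sequence]) -> tuple[str, str]:
    groups = list(profiles_by_group)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    for g in groups:
        if len(profiles_by_group[g]) < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicate samples for a t-test")
    return groups[0], groups[1]


def compare_class_rates(
    profiles_by_group: Mapping[str, Sequence[ErrorProfile]],
    alpha: float = 0.01,
    collapsed: bool = False,
) -> pd.DataFrame:
    """Welch t-test per substitution class between two sample groups.

    Returns one row per class (12 directional or 6 collapsed) with group
    means +/- SD, raw and Bonferroni-adjusted p, a significance flag at
    ``alpha`` (on the adjusted p), and the direction of the difference; a
    final ``total`` row tests the total rate separately (unadjusted).
    """
    ga, gb = _two_groups(profiles_by_group)
    if collapsed:
        labels = list(COLLAPSED_CLASSES)
        extract = lambda p: [p.collapsed_rates[c] for c in labels]  # noqa: E731
    else:
        labels = [str(c) for c in ALL_CLASSES]
        extract = lambda p: [p.rates[c] for c in ALL_CLASSES]  # noqa: E731
    a = np.array([extract(p) for p in profiles_by_group[ga]], dtype=float).T
    b = np.array([extract(p) for p in profiles_by_group[gb]], dtype=float).T
    t, p = _welch_rows(a, b)
    m = len(labels)
    rows = pd.DataFrame({
        "class": labels,
        f"mean_{ga}": a.mean(axis=1),
        f"sd_{ga}": a.std(axis=1, ddof=1),
        f"mean_{gb}": b.mean(axis=1),
        f"sd_{gb}": b.std(axis=1, ddof=1),
        "t": t,
        "p": p,
        "p_adj": np.minimum(1.0, p * m),
    })
    tot_a = np.array([[pr.total_rate for pr in profiles_by_group[ga]]])
    tot_b = np.array([[pr.total_rate for pr in profiles_by_group[gb]]])
    tt, tp = _welch_rows(tot_a, tot_b)
    rows = pd.concat([rows, pd.DataFrame({
        "class": ["total"],
        f"mean_{ga}": tot_a.mean(axis=1), f"sd_{ga}": tot_a.std(axis=1, ddof=1),
        f"mean_{gb}": tot_b.mean(axis=1), f"sd_{gb}": tot_b.std(axis=1, ddof=1),
        "t": tt, "p": tp, "p_adj": tp,
    })], ignore_index=True)
    rows["significant"] = rows["p_adj"] < alpha
    rows["direction"] = np.where(
        rows[f"mean_{ga}"] > rows[f"mean_{gb}"], f"{ga}>{gb}",
        np.where(rows[f"mean_{ga}"] < rows[f"mean_{gb}"], f"{gb}>{ga}", "equal"),
    )
    return rows


@dataclass
class PositionHitList:
    """Positions whose per-class error rates differ between groups."""

    hits: pd.DataFrame  # chrom,pos,ref,class,mean_<a>,mean_<b>,direction,p,p_adj
    n_tested: dict[str, int]  # per reference base
    n_untestable: int
    groups: tuple[str, str]
    alpha: float
    correction: str

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def fraction(self) -> float:
        total = sum(self.n_tested.values())
        return self.n_hits / total if total else float("nan")

    def hit_positions(self) -> frozenset:
        return frozenset(zip(self.hits["chrom"], self.hits["pos"].astype(int)))

    def to_bed(self, path) -> None:
        bed = self.hits.assign(start=self.hits["pos"], end=self.hits["pos"] + 1)
        bed["name"] = bed["class"] + ":" + bed["direction"]
        bed[["chrom", "start", "end", "name"]].to_csv(
            path, sep="\t", header=False, index=False)


def compare_positions(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> PositionHitList:
    """Welch t-test per (position, class) between the two groups.

    ``table`` is the long per-position table from
    :func:`bgerr.profiling.position_error_table` (the directional-class rows
    are used; the pooled ``total`` rows are ignored here).  ``groups`` maps
    sample_id to group label.  Correction (``bonferroni`` | ``bh`` |
    ``none``) is applied within each reference-base family.  Positions where
    both groups have zero variance and equal means count as untestable.
    """
    if correction not in ("bonferroni", "bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    df = table[table["class"] != "total"]
    wide = df.pivot_table(index=["chrom", "pos", "ref", "class"],
                          columns="sample_id", values="rate")
    sample_ids = list(wide.columns)
    labels = {groups[s] for s in sample_ids}
    if len(labels) != 2:
        raise ValueError(f"expected 2 groups, got {sorted(labels)}")
    ga, gb = sorted(labels)
    a_cols = [s for s in sample_ids if groups[s] == ga]
    b_cols = [s for s in sample_ids if groups[s] == gb]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >= 2 samples for per-position tests")
    a = wide[a_cols].to_numpy(dtype=float)
    b = wide[b_cols].to_numpy(dtype=float)
    complete = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
    a, b = a[complete], b[complete]
    idx = wide.index[complete]
    t, p = _welch_rows(a, b)
    untestable = (p == 1.0) & (t == 0.0)

    refs = idx.get_level_values("ref").to_numpy()
    p_adj = np.ones_like(p)
    n_tested: dict[str, int] = {}
    for ref in BASES:
        fam = (refs == ref) & ~untestable
        m = int(fam.sum())
        n_tested[ref] = m
        if m == 0:
            continue
        if correction == "bonferroni":
            p_adj[fam] = np.minimum(1.0, p[fam] * m)
        elif correction == "bh":
            p_adj[fam] = stats.false_discovery_control(p[fam], method="bh")
        else:
            p_adj[fam] = p[fam]
    is_hit = ~untestable & (p_adj < alpha)
    hits = pd.DataFrame({
        "chrom": idx.get_level_values("chrom")[is_hit],
        "pos": idx.get_level_values("pos")[is_hit],
        "ref": refs[is_hit],
        "class": idx.get_level_values("class")[is_hit],
        f"mean_{ga}": a[is_hit].mean(axis=1),
        f"mean_{gb}": b[is_hit].mean(axis=1),
        "p": p[is_hit],
        "p_adj": p_adj[is_hit],
    })
    hits["direction"] = np.where(
        hits[f"mean_{ga}"] > hits[f"mean_{gb}"], f"{ga}>{gb}", f"{gb}>{ga}")
    hits = hits.sort_values(["chrom", "pos", "class"]).reset_index(drop=True)
    return PositionHitList(
        hits=hits,
        n_tested=n_tested,
        n_untestable=int(untestable.sum()) + int((~complete).sum()),
        groups=(ga, gb),
        alpha=alpha,
        correction=correction,
    )


def exclude_and_reprofile(
    positions: Iterable[tuple[str, int]],
    counts_by_sample: Mapping[str, pd.DataFrame],
    filt: FilterConfig,
    masks_by_sample: Mapping[str, MaskSet] | None = None,
    pair_depths_by_sample: Mapping[str, Sequence[pd.DataFrame]] | None = None,
) -> tuple[dict[str, ErrorProfile], dict[str, ErrorProfile], pd.DataFrame]:
    """Re-profile every sample after removing a set of genomic positions.

    Returns (profiles_before, profiles_after, deltas) where ``deltas`` has
    one row per sample x class (plus ``total``) with the rates before and
    after exclusion and the relative change ``(after - before) / before``.
    An empty position list is an identity; excluding everything yields
    undefined (NaN) rates, reported as missing.
    """
    excl = frozenset((c, int(p)) for c, p in positions)
    masks_by_sample = masks_by_sample or {}
    pair_depths_by_sample = pair_depths_by_sample or {}
    before: dict[str, ErrorProfile] = {}
    after: dict[str, ErrorProfile] = {}
    rows = []
    for sid, counts in counts_by_sample.items():
        mask = masks_by_sample.get(sid, frozenset())
        pair = pair_depths_by_sample.get(sid)
        before[sid] = compute_error_profile(counts, filt, sid, mask, pair)
        after[sid] = compute_error_profile(
            counts, filt, sid, mask, pair, exclude_positions=excl)
        rb, ra = before[sid].rates, after[sid].rates
        for c in ALL_CLASSES:
            rel = (ra[c] - rb[c]) / rb[c] if rb[c] and rb[c] == rb[c] else float("nan")
            rows.append({"sample_id": sid, "class": str(c),
                         "rate_before": rb[c], "rate_after": ra[c], "rel_change": rel})
        tb, ta = before[sid].total_rate, after[sid].total_rate
        rel = (ta - tb) / tb if tb and tb == tb else float("nan")
        rows.append({"sample_id": sid, "class": "total",
                     "rate_before": tb, "rate_after": ta, "rel_change": rel})
    return before, after, pd.DataFrame(rows)


def compare_bins(
    bin_profiles_by_group: Mapping[str, Sequence[FragmentBinProfile]],
    alpha: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Breakpoint-bin contrasts within and between groups.

    Within each group: the total error rate of bin 1 against the pooled
    per-sample rates of bins 2-10, and, per directional class, bin 1 against
    bin 2 and bin 1 against bins 2-10 (Bonferroni across the 12 classes).
    Across groups: per class, the per-sample end-elevation contrast
    (bin-1 rate minus the mean of bins 2-10) compared between groups,
    Bonferroni across classes.
    """
    ga, gb = _two_groups(bin_profiles_by_group)

    def stack_totals(profiles):  # (n_samples, 10)
        return np.array([p.total_bin_rates().to_numpy(dtype=float) for p in profiles])

    total_rows = []
    for g in (ga, gb):
        totals = stack_totals(bin_profiles_by_group[g])
        if np.isnan(totals).any():
            raise ValueError(f"group {g!r} has bins with no eligible bases")
        t, p = _welch_rows(totals[:, 0][None, :], totals[:, 1:].reshape(1, -1))
        total_rows.append({"group": g, "mean_bin1": totals[:, 0].mean(),
                           "mean_rest": totals[:, 1:].mean(), "t": t[0], "p": p[0],
                           "significant": p[0] < alpha})
    out: dict[str, pd.DataFrame] = {"total_bin1_vs_rest": pd.DataFrame(total_rows)}

    for prefix, labels, table in (
        ("class", [str(c) for c in ALL_CLASSES], lambda p: p.bin_rates),
        ("collapsed", list(COLLAPSED_CLASSES), lambda p: p.collapsed_bin_rates()),
    ):
        m = len(labels)
        b1_rest_rows, b1_b2_rows = [], []
        contrasts = {}
        for g in (ga, gb):
            rates = np.array([table(p)[labels].to_numpy(dtype=float)
                              for p in bin_profiles_by_group[g]])  # (n, 10, m)
            if np.isnan(rates).any():
                raise ValueError(f"group {g!r} has bins with no eligible bases")
            bin1 = rates[:, 0, :].T          # (m, n)
            bin2 = rates[:, 1, :].T
            rest_flat = np.transpose(rates[:, 1:, :], (2, 0, 1)).reshape(m, -1)
            for name, other, store in (("bins2-10", rest_flat, b1_rest_rows),
                                       ("bin2", bin2, b1_b2_rows)):
                t, p = _welch_rows(bin1, other)
                p_adj = np.minimum(1.0, p * m)
                for i, cls in enumerate(labels):
                    store.append({"group": g, "class": cls,
                                  "mean_bin1": bin1[i].mean(),
                                  f"mean_{name}": other[i].mean(),
                                  "t": t[i], "p": p[i], "p_adj": p_adj[i],
                                  "significant": p_adj[i] < alpha})
            contrasts[g] = rates[:, 0, :] - rates[:, 1:, :].mean(axis=1)  # (n, m)
        t, p = _welch_rows(contrasts[ga].T, contrasts[gb].T)
        p_adj = np.minimum(1.0, p * m)
        group_rows = [{"class": cls,
                       f"mean_contrast_{ga}": contrasts[ga][:, i].mean(),
                       f"mean_contrast_{gb}": contrasts[gb][:, i].mean(),
                       "t": t[i], "p": p[i], "p_adj": p_adj[i],
                       "significant": p_adj[i] < alpha}
                      for i, cls in enumerate(labels)]
        out[f"{prefix}_bin1_vs_rest"] = pd.DataFrame(b1_rest_rows)
        out[f"{prefix}_bin1_vs_bin2"] = pd.DataFrame(b1_b2_rows)
        out[f"{prefix}_group_contrast"] = pd.DataFrame(group_rows)
    return out


def replicate_concordance(
    profiles_rep1: Sequence[ErrorProfile],
    profiles_rep2: Sequence[ErrorProfile],
) -> pd.DataFrame:
    """Per-class absolute difference of mean rates between technical duplicates.

    Returns one row per directional class plus ``total`` with the replicate
    means and ``abs_diff``; the maximum across classes quantifies technical
    variability.  Raises if the replicate sets are unpaired (different
    sizes or empty).
    """
    if not profiles_rep1 or len(profiles_rep1) != len(profiles_rep2):
        raise ValueError("replicate sets must be non-empty and of equal size")
    rows = []
    for c in ALL_CLASSES:
        m1 = float(np.mean([p.rates[c] for p in profiles_rep1]))
        m2 = float(np.mean([p.rates[c] for p in profiles_rep2]))
        rows.append({"class": str(c), "mean_rep1": m1, "mean_rep2": m2,
                     "abs_diff": abs(m1 - m2)})
    t1 = float(np.mean([p.total_rate for p in profiles_rep1]))
    t2 = float(np.mean([p.total_rate for p in profiles_rep2]))
    rows.append({"class": "total", "mean_rep1": t1, "mean_rep2": t2,
                 "abs_diff": abs(t1 - t2)})
    return pd.DataFrame(rows)


__all__ = [
    "compare_class_rates",
    "PositionHitList",
    "compare_positions",
    "exclude_and_reprofile",
    "compare_bins",
    "replicate_concordance",
]
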