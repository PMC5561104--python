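"""Per-site correlation between a reference factor's signal and candidate cofactors.

Co-occupancy is scored descriptively: for every binding site the Pearson
correlation between the site's binned signal profile (200 bins at defaults)
of the factor of interest and of each candidate cofactor, computed on
normalized, context-matched profiles.  Sites where either profile is flat
(zero variance) carry no shape information and are excluded, not
zero-imputed.  Averaging r within co-occurrence classes and ranking sites by
mean cofactor correlation reproduce the standard downstream summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import CooccurrenceClassing
from .signal import BinCountMatrix


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r per row of two equally shaped matrices; NaN where either row
    has zero variance."""
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean(axis=1, keepdims=True)
    num = (xm * ym).sum(axis=1)
    den = np.sqrt((xm ** 2).sum(axis=1) * (ym ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def pearson_per_site(
    ref: BinCountMatrix,
    factor: BinCountMatrix,
    *,
    ref_label: str | None = None,
    factor_label: str | None = None,
    concatenated: bool = False,
) -> pd.DataFrame:
    """Per-site Pearson r between two profiles sharing the bin scheme.

    Both matrices must have the same (site_id, bin_index) row universe.
    Returns a DataFrame ``site_id, r`` (NaN where either site profile has
    zero variance).  With ``concatenated=True`` a single r over all bins of
    all sites is returned instead (one-row frame, site_id ``"__all__"``).
    """
    if not ref.same_rows(factor):
        raise ValueError("profiles do not share the same (site, bin) universe")
    ref_label = ref_label or ref.labels[0]
    factor_label = factor_label or factor.labels[0]
    x = ref.site_profiles(ref_label)
    y = factor.site_profiles(factor_label)
    if concatenated:
        r = _rowwise_pearson(x.reshape(1, -1), y.reshape(1, -1))
        return pd.DataFrame({"site_id": ["__all__"], "r": r})
    return pd.DataFrame({"site_id": ref.site_ids, "r": _rowwise_pearson(x, y)})


def correlation_table(
    ref: BinCountMatrix,
    factors: Mapping[str, BinCountMatrix] | BinCountMatrix,
    *,
    ref_label: str | None = None,
) -> pd.DataFrame:
    """Long-form table ``site_id, factor, r`` over candidate cofactors.

    ``factors`` is either a mapping name → single-column profile matrix or
    one multi-column matrix whose remaining columns are the candidates.
    """
    frames = []
    if isinstance(factors, BinCountMatrix):
        ref_lab = ref_label or ref.labels[0]
        for lab in factors.labels:
            if lab == ref_lab and factors is ref:
                continue
            t = pearson_per_site(ref, factors, ref_label=ref_lab, factor_label=lab)
            t.insert(1, "factor", lab)
            frames.append(t)
    else:
        for name, fm in factors.items():
            t = pearson_per_site(ref, fm, ref_label=ref_label)
            t.insert(1, "factor", name)
            frames.append(t)
    if not frames:
        raise ValueError("no candidate factors")
    return pd.concat(frames, ignore_index=True)


def subset_mean(
    correlations: pd.DataFrame,
    classing: CooccurrenceClassing | Mapping[str, str],
    *,
    site_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean r per (factor, co-occurrence class); NaN r excluded from means.

    ``classing`` is a :class:`CooccurrenceClassing` (aligned with *site_ids*
    or with the table's unique site order) or a mapping site_id → class.
    Classes with zero valid sites are kept with NaN mean and n_valid = 0.
    """
    if isinstance(classing, CooccurrenceClassing):
        ids = list(site_ids) if site_ids is not None else list(
            dict.fromkeys(correlations["site_id"]))
        if len(ids) != len(classing):
            raise ValueError("classing does not cover the site universe")
        class_of = dict(zip(ids, classing.labels))
    else:
        class_of = dict(classing)
    df = correlations.copy()
    try:
        df["class"] = [class_of[s] for s in df["site_id"]]
    except KeyError as exc:
        raise ValueError(f"site {exc.args[0]!r} missing from classing") from None

    rows = []
    for (factor, cls), grp in df.groupby(["factor", "class"], sort=True):
        valid = grp["r"].dropna()
        rows.append({"factor": factor, "class": cls,
                     "mean_r": valid.mean() if len(valid) else np.nan,
                     "n_valid": int(len(valid))})
    return pd.DataFrame(rows)


def rank_sites_by_cofactor_support(
    correlations: pd.DataFrame,
    factors: Sequence[str],
) -> pd.DataFrame:
    """Rank sites by mean r across selected cofactors; assign quartiles.

    Returns ``site_id, mean_r, rank, quartile`` sorted by rank (1 = highest
    mean r; ties broken by first appearance of the site in the input table).
    Sites with no defined r for any selected factor are excluded and listed
    with rank and quartile NA at the bottom.
    """
    if not factors:
        raise ValueError("select at least one factor")
    sel = correlations[correlations["factor"].isin(set(factors))]
    if sel.empty:
        raise ValueError("selected factors absent from the correlation table")
    order = list(dict.fromkeys(correlations["site_id"]))
    means = sel.groupby("site_id")["r"].mean()   # NaN-skipping mean
    mean_r = np.array([means.get(s, np.nan) for s in order])

    ranked_idx = [i for i in np.argsort(-np.where(np.isnan(mean_r), -np.inf, mean_r),
                                        kind="stable")
                  if not np.isnan(mean_r[i])]
    unranked_idx = [i for i in range(len(order)) if np.isnan(mean_r[i])]

    n = len(ranked_idx)
    rows = []
    for pos, i in enumerate(ranked_idx):
        rows.append({"site_id": order[i], "mean_r": mean_r[i],
                     "rank": pos + 1, "quartile": f"Q{pos * 4 // n + 1}"})
    for i in unranked_idx:
        rows.append({"site_id": order[i], "mean_r": np.nan,
                     "rank": pd.NA, "quartile": pd.NA})
    return pd.DataFrame(rows)
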