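"""Instrument scoring, missing-item imputation and eligibility filtering.

Scoring follows the study protocol: AQ items dichotomised by the
published key and summed 0–50 (flag strict at > 32); TAS-20 reverse
items mapped r -> 6 - r, subscale sums DIF/DDF/EOT and total with the
clinical flag at >= 61; BDI summed 0–63 and banded (11–17
mild-moderate, >= 18 clinical). Missing items are replaced by the mean
response of the participant's diagnostic group for that item (AQ on the
recoded 0/1 scale by default, since AQ totals are sums of recoded
items). Eligibility excludes total IQ <= 70, four or more missing items
on AQ or TAS-20, and AQ totals more than 3 SD *below* the analysis-set
mean — applied in that order, with reasons recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .keys import AQ_N_ITEMS, DEFAULT_KEYS, InstrumentKeys

SCORE_COLS = ["aq", "dif", "ddf", "eot", "tas_total", "bdi",
              "aq_flag", "tas_flag", "bdi_band"]


@dataclass
class EligibilityReport:
    """Retained/excluded participant ids with exclusion reason codes."""

    retained_ids: list
    excluded: dict  # id -> reason in {low_IQ, too_many_missing, aq_low_outlier}

    @property
    def excluded_ids(self) -> list:
        return list(self.excluded)


def impute_missing_items(
    table: pd.DataFrame,
    group_col: str = "group",
    instruments: tuple[str, ...] = ("aq", "tas", "bdi"),
) -> pd.DataFrame:
    """Replace missing item cells by per-item means within diagnostic group.

    Operates on raw response scales (for AQ the default pipeline imputes
    *after* recoding instead — see :func:`score_cohort`). Observed cells
    are never altered; a group with no observed response on an item
    cannot be imputed and raises ``ValueError``.
    """
    out = table.copy()
    for inst in instruments:
        cols = io.item_columns(inst)
        vals = out[cols].astype(float)
        group_means = vals.groupby(out[group_col]).transform("mean")
        if vals.isna().to_numpy().any() and group_means.isna().to_numpy().any():
            bad = group_means.columns[group_means.isna().any()].tolist()
            raise ValueError(f"no observed responses to impute from: {bad}")
        out[cols] = vals.where(~vals.isna(), group_means)
    return out


def recode_aq(items: np.ndarray, keys: InstrumentKeys = DEFAULT_KEYS) -> np.ndarray:
    """Dichotomise raw 1–4 AQ responses to 0/1 in the autism direction.

    Agree-keyed items score 1 for responses 1–2, disagree-keyed for 3–4.
    Fractional (imputed) values are passed through untouched only if the
    input is already on the 0/1 scale; raw responses must be in 1–4.
    Missing cells propagate as NaN.
    """
    arr = np.asarray(items, dtype=float)
    present = ~np.isnan(arr)
    if ((arr[present] < 1) | (arr[present] > 4)).any():
        raise ValueError("AQ responses must lie in 1..4")
    agree = np.array([i in keys.aq_agree_keyed for i in range(1, AQ_N_ITEMS + 1)])
    endorsed_low = arr <= 2.5  # responses 1-2
    recoded = np.where(agree[None, :], endorsed_low, ~endorsed_low).astype(float)
    recoded[~present] = np.nan
    return recoded


def score_aq(
    items: np.ndarray, keys: InstrumentKeys = DEFAULT_KEYS,
    already_recoded: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """AQ total (0–50, fractional after imputation) and strict > 32 flag."""
    arr = np.asarray(items, dtype=float)
    if not already_recoded:
        arr = recode_aq(arr, keys)
    elif ((arr[~np.isnan(arr)] < 0) | (arr[~np.isnan(arr)] > 1)).any():
        raise ValueError("recoded AQ values must lie in [0, 1]")
    score = arr.sum(axis=1)
    return score, score > keys.aq_cutoff


def score_tas20(
    items: np.ndarray, keys: InstrumentKeys = DEFAULT_KEYS
) -> pd.DataFrame:
    """TAS-20 subscales, total and clinical flag (total >= 61).

    Reverse-keyed items {4, 5, 10, 18, 19} are mapped r -> 6 - r before
    summation; DIF/DDF/EOT partition the 20 items.
    """
    arr = np.asarray(items, dtype=float)
    present = ~np.isnan(arr)
    if ((arr[present] < 1) | (arr[present] > 5)).any():
        raise ValueError("TAS-20 responses must lie in 1..5")
    scored = arr.copy()
    for item in keys.tas_reverse:
        scored[:, item - 1] = 6.0 - scored[:, item - 1]
    dif = scored[:, [i - 1 for i in keys.tas_dif]].sum(axis=1)
    ddf = scored[:, [i - 1 for i in keys.tas_ddf]].sum(axis=1)
    eot = scored[:, [i - 1 for i in keys.tas_eot]].sum(axis=1)
    total = dif + ddf + eot
    return pd.DataFrame({
        "dif": dif, "ddf": ddf, "eot": eot, "tas_total": total,
        "tas_flag": total >= keys.tas_cutoff,
    })


def score_bdi(
    items: np.ndarray, keys: InstrumentKeys = DEFAULT_KEYS
) -> tuple[np.ndarray, np.ndarray]:
    """BDI total (0–63) and severity band.

    Bands: ``minimal`` (< 11), ``mild-moderate`` (11–17), ``clinical``
    (>= 18).
    """
    arr = np.asarray(items, dtype=float)
    present = ~np.isnan(arr)
    if ((arr[present] < 0) | (arr[present] > 3)).any():
        raise ValueError("BDI responses must lie in 0..3")
    score = arr.sum(axis=1)
    band = np.where(score >= keys.bdi_clinical, "clinical",
                    np.where(score >= keys.bdi_mild_low, "mild-moderate",
                             "minimal"))
    return score, band


def score_cohort(
    table: pd.DataFrame,
    keys: InstrumentKeys = DEFAULT_KEYS,
    aq_impute_scale: str = "recoded",
    impute: bool = True,
) -> pd.DataFrame:
    """Score a full item-level cohort table.

    Adds ``aq, dif, ddf, eot, tas_total, bdi`` plus flag/band columns.
    Missing items are imputed by group means first; ``aq_impute_scale``
    chooses whether AQ imputation happens on the recoded 0/1 scale
    (default — AQ totals are sums of recoded items) or on the raw 1–4
    responses.
    """
    io.validate_item_table(table)
    if aq_impute_scale not in ("recoded", "raw"):
        raise ValueError("aq_impute_scale must be 'recoded' or 'raw'")
    out = table.copy()

    if impute:
        if aq_impute_scale == "raw":
            out = impute_missing_items(out, instruments=("aq", "tas", "bdi"))
            aq_mat = recode_aq(out[io.AQ_COLS].to_numpy(dtype=float), keys)
        else:
            out = impute_missing_items(out, instruments=("tas", "bdi"))
            aq_mat = recode_aq(out[io.AQ_COLS].to_numpy(dtype=float), keys)
            aq_df = pd.DataFrame(aq_mat, index=out.index)
            group_means = aq_df.groupby(out["group"]).transform("mean")
            aq_mat = aq_df.where(~aq_df.isna(), group_means).to_numpy()
    else:
        aq_mat = recode_aq(out[io.AQ_COLS].to_numpy(dtype=float), keys)

    aq, aq_flag = score_aq(aq_mat, keys, already_recoded=True)
    tas = score_tas20(out[io.TAS_COLS].to_numpy(dtype=float), keys)
    bdi, band = score_bdi(out[io.BDI_COLS].to_numpy(dtype=float), keys)

    out["aq"] = aq
    out["aq_flag"] = aq_flag
    for col in ("dif", "ddf", "eot", "tas_total", "tas_flag"):
        out[col] = tas[col].to_numpy()
    out["bdi"] = bdi
    out["bdi_band"] = band
    return out


def apply_eligibility(
    table: pd.DataFrame,
    scored: pd.DataFrame | None = None,
    iq_col: str | None = None,
    outlier_sd: float = 3.0,
) -> EligibilityReport:
    """Eligibility filter: IQ, missing-item census, AQ low outliers.

    Order of application mirrors the study: (1) exclude total IQ <= 70
    (strict > 70 retained); total IQ is the mean of PIQ and VIQ when no
    composite column is given; (2) exclude >= 4 missing items on AQ or
    TAS-20 (counted pre-imputation); (3) exclude AQ totals more than
    ``outlier_sd`` SDs *below* the AQ mean of the rows surviving (1)–(2)
    — low side only. Each exclusion records its (first) reason.
    """
    ids = table["id"].tolist()
    excluded: dict = {}

    iq = (table[iq_col] if iq_col
          else (table["piq"] + table["viq"]) / 2.0)
    for pid, value in zip(ids, iq):
        if not value > 70:
            excluded[pid] = "low_IQ"

    aq_missing = table[io.AQ_COLS].isna().sum(axis=1)
    tas_missing = table[io.TAS_COLS].isna().sum(axis=1)
    for pid, na, nt in zip(ids, aq_missing, tas_missing):
        if pid not in excluded and (na >= 4 or nt >= 4):
            excluded[pid] = "too_many_missing"

    scored = scored if scored is not None else table
    if "aq" not in scored.columns:
        raise ValueError("AQ totals required for outlier screening; "
                         "score the cohort first")
    surviving = scored[~scored["id"].isin(excluded)]
    mean_aq = surviving["aq"].mean()
    sd_aq = surviving["aq"].std(ddof=1)
    cutoff = mean_aq - outlier_sd * sd_aq
    for pid, score in zip(surviving["id"], surviving["aq"]):
        if score < cutoff:
            excluded[pid] = "aq_low_outlier"

    retained = [pid for pid in ids if pid not in excluded]
    return EligibilityReport(retained_ids=retained, excluded=excluded)


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total
    variance), sample variances with the n-1 denominator."""
    arr = np.asarray(item_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 items")
    if np.isnan(arr).any():
        arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 complete rows")
    k = arr.shape[1]
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance")
    item_vars = arr.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_vars / total_var)
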