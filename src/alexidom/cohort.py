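"""Seeded synthetic cohorts with the moment structure of the clinical study.

The study population is adults referred to an outpatient autism clinic,
split into a confirmed-diagnosis group (ASD+, n = 281) and a ruled-out
group (ASD-, n = 119). No raw data are public, so this module generates
cohorts that reproduce the published summary structure:

* group-specific means and SDs of BDI, AQ, DIF, DDF, EOT, age, PIQ, VIQ;
* the per-group 5x5 correlation matrix over (BDI, AQ, DIF, DDF, EOT);
* item-level internal consistencies (Cronbach's alpha) per instrument;
* group-specific sex ratios and sparse item-level missingness.

Generative model
----------------
Scale scores are multivariate normal latents (demographics independent
of the five scales, since their cross-correlations are not published).
Item responses come from a one-factor model per instrument: each item is
``lambda * F + s * q_perm`` where ``F`` is the participant's standardized
latent scale score and the residuals are a per-participant random
permutation of fixed stratified normal quantiles. The permuted-quantile
residuals sum to zero exactly, so the item *sum* tracks the latent scale
score almost perfectly while pairwise inter-item correlations — and
hence alpha — are controlled by the loading. Items are discretised by
normal-quantile thresholds whose location is solved so the expected item
sum matches the target scale mean; the discretisation attenuation of
inter-item correlation is compensated in closed form.

Determinism: one master seed; each (group, stage) pair draws from
``numpy.random.SeedSequence(master, spawn_key=(group_index, stage))``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io
from .keys import AQ_N_ITEMS, DEFAULT_KEYS, InstrumentKeys

#: order of the five scales in every correlation matrix
SCALE_ORDER = ("bdi", "aq", "dif", "ddf", "eot")

_STAGE = {"latent": 0, "aq": 1, "dif": 2, "ddf": 3, "eot": 4, "bdi": 5,
          "missing": 6, "rawsplit": 7}

_TAS_SUBSCALES = {"dif": (7, (1, 5)), "ddf": (5, (1, 5)), "eot": (8, (1, 5))}


def stage_rng(master_seed: int, group_index: int, stage: str) -> np.random.Generator:
    """Child generator for one (group, pipeline stage) pair."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, _STAGE[stage]))
    return np.random.default_rng(ss)


@dataclass
class GroupSpec:
    """Target population structure for one diagnostic group.

    ``corr`` is the 5x5 correlation matrix over :data:`SCALE_ORDER`;
    ``scale_means``/``scale_sds`` cover the five scales plus ``age``,
    ``piq`` and ``viq``; ``alphas`` are target Cronbach's alphas per
    instrument (sub)scale; ``missing_rate`` is the per-cell probability
    of a missing AQ/TAS item response.
    """

    group_label: str
    n: int
    scale_means: dict[str, float]
    scale_sds: dict[str, float]
    corr: np.ndarray
    male_fraction: float
    alphas: dict[str, float]
    missing_rate: float = 0.002
    heteroscedastic_bdi: bool = False
    het_gamma: float = 0.8  # BDI noise-SD slope on z(DIF) when heteroscedastic

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n < 7:  # number of model predictors + 2 at minimum
            raise ValueError("group size too small for the analysis model")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.corr.shape != (len(SCALE_ORDER),) * 2:
            raise ValueError("corr must be 5x5 over (bdi, aq, dif, ddf, eot)")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise ValueError("corr must have a unit diagonal")
        for name in SCALE_ORDER + ("age", "piq", "viq"):
            if name not in self.scale_means or name not in self.scale_sds:
                raise ValueError(f"scale_means/scale_sds must include {name!r}")
            if self.scale_sds[name] <= 0:
                raise ValueError(f"SD for {name!r} must be positive")
        for scale, a in self.alphas.items():
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha for {scale!r} must lie in (0, 1)")


# Published group summaries: means (SDs) per scale, male/female counts,
# per-(sub)scale internal consistencies. The BDI alpha is not reported
# with the study and defaults to a typical published value for the
# instrument (0.88).
_ASD_PLUS = dict(
    group_label="ASD+",
    n=281,
    scale_means={"bdi": 13.9, "aq": 38.7, "dif": 22.1, "ddf": 19.1,
                 "eot": 23.4, "age": 33.2, "piq": 99.7, "viq": 107.0},
    scale_sds={"bdi": 10.4, "aq": 6.1, "dif": 6.1, "ddf": 3.8,
               "eot": 5.2, "age": 11.0, "piq": 16.3, "viq": 16.4},
    corr=np.array([
        [1.00, 0.25, 0.41, 0.26, -0.03],
        [0.25, 1.00, 0.52, 0.47, 0.00],
        [0.41, 0.52, 1.00, 0.59, 0.08],
        [0.26, 0.47, 0.59, 1.00, 0.22],
        [-0.03, 0.00, 0.08, 0.22, 1.00],
    ]),
    male_fraction=219 / 281,
    alphas={"aq": 0.86, "dif": 0.85, "ddf": 0.74, "eot": 0.60, "bdi": 0.88},
)

_ASD_MINUS = dict(
    group_label="ASD-",
    n=119,
    scale_means={"bdi": 15.7, "aq": 37.6, "dif": 23.2, "ddf": 18.9,
                 "eot": 23.7, "age": 33.5, "piq": 98.0, "viq": 101.8},
    scale_sds={"bdi": 10.5, "aq": 5.8, "dif": 6.6, "ddf": 4.0,
               "eot": 5.1, "age": 12.5, "piq": 14.1, "viq": 15.2},
    corr=np.array([
        [1.00, 0.12, 0.25, -0.01, 0.06],
        [0.12, 1.00, 0.44, 0.47, 0.02],
        [0.25, 0.44, 1.00, 0.61, -0.01],
        [-0.01, 0.47, 0.61, 1.00, 0.17],
        [0.06, 0.02, -0.01, 0.17, 1.00],
    ]),
    male_fraction=81 / 119,
    alphas={"aq": 0.86, "dif": 0.85, "ddf": 0.74, "eot": 0.60, "bdi": 0.88},
)


def default_group_specs(
    overrides: Mapping[str, Mapping[str, Any]] | None = None,
) -> tuple[GroupSpec, GroupSpec]:
    """Specs populated with the published ASD+ / ASD- group summaries.

    ``overrides`` maps a group label to field replacements, e.g.
    ``{"ASD+": {"n": 50}}`` — all other fields keep their defaults.
    """
    specs = []
    for base in (_ASD_PLUS, _ASD_MINUS):
        kw = dict(base)
        kw["corr"] = np.array(base["corr"], copy=True)
        kw["scale_means"] = dict(base["scale_means"])
        kw["scale_sds"] = dict(base["scale_sds"])
        kw["alphas"] = dict(base["alphas"])
        if overrides and base["group_label"] in overrides:
            valid = {f.name for f in fields(GroupSpec)}
            for key, value in overrides[base["group_label"]].items():
                if key not in valid:
                    raise KeyError(f"unknown GroupSpec field {key!r}")
                if isinstance(kw.get(key), dict):
                    kw[key] = {**kw[key], **value}
                else:
                    kw[key] = value
        specs.append(GroupSpec(**kw))
    return specs[0], specs[1]


def make_correlation_psd(corr: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Repair a user-edited correlation matrix to positive semi-definite.

    Eigenvalues are clipped at ``floor``, the matrix reassembled and
    rescaled back to a unit diagonal. An already-PSD input is returned
    unchanged. Non-symmetric or non-unit-diagonal input is rejected.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() >= 0.0:
        return corr
    clipped = np.maximum(eigval, floor)
    repaired = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def generate_latent_cohort(
    spec: GroupSpec, seed: int, group_index: int = 0
) -> pd.DataFrame:
    """Continuous scale scores + demographics for one group.

    The five scales are drawn from a multivariate normal with the spec's
    moments; age is a truncated normal (>= 18, adult clinic), PIQ/VIQ
    independent normals, sex Bernoulli(male_fraction). With
    ``spec.heteroscedastic_bdi`` the BDI error variance scales with
    standardized DIF (its conditional mean given the four traits is
    preserved), emulating the funnel-shaped residuals the analysis
    pipeline must detect.
    """
    eigmin = np.linalg.eigvalsh(spec.corr).min()
    if eigmin < -1e-10:
        raise ValueError(
            "correlation matrix is not PSD; repair it with make_correlation_psd")
    rng = stage_rng(seed, group_index, "latent")
    n = spec.n
    sds = np.array([spec.scale_sds[s] for s in SCALE_ORDER])
    means = np.array([spec.scale_means[s] for s in SCALE_ORDER])
    cov = spec.corr * np.outer(sds, sds)
    scales = rng.multivariate_normal(means, cov, size=n, method="eigh")

    if spec.heteroscedastic_bdi:
        # BDI = E[BDI | traits] + noise whose SD is linear in z(DIF),
        # normalised so the average noise variance matches the MVN's
        # conditional variance (keeps marginal moments approximately).
        traits = scales[:, 1:]
        c_bt = cov[0, 1:]
        c_tt = cov[1:, 1:]
        w = np.linalg.solve(c_tt, c_bt)
        cond_mean = means[0] + (traits - means[1:]) @ w
        cond_var = cov[0, 0] - c_bt @ w
        z_dif = (scales[:, 2] - means[2]) / sds[2]
        g = np.maximum(1.0 + spec.het_gamma * z_dif, 0.1)
        g = g / np.sqrt(1.0 + spec.het_gamma**2)
        scales[:, 0] = cond_mean + rng.standard_normal(n) * np.sqrt(cond_var) * g

    age_lo = (18.0 - spec.scale_means["age"]) / spec.scale_sds["age"]
    age = stats.truncnorm.rvs(
        age_lo, np.inf, loc=spec.scale_means["age"],
        scale=spec.scale_sds["age"], size=n, random_state=rng)
    piq = rng.normal(spec.scale_means["piq"], spec.scale_sds["piq"], n)
    viq = rng.normal(spec.scale_means["viq"], spec.scale_sds["viq"], n)
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")

    out = pd.DataFrame({
        "group": spec.group_label, "age": age, "sex": sex,
        "piq": piq, "viq": viq,
    })
    for j, name in enumerate(SCALE_ORDER):
        out[name] = scales[:, j]
    return out


def implied_interitem_r(alpha: float, k: int) -> float:
    """Mean inter-item correlation implied by alpha for k items
    (Spearman–Brown inversion: r = alpha / (k - alpha (k-1)))."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("target alpha must lie in (0, 1)")
    if k < 2:
        raise ValueError("need at least 2 items")
    r = alpha / (k - alpha * (k - 1))
    if not 0.0 < r < 1.0:
        raise ValueError(f"alpha {alpha} incompatible with {k} items")
    return r


def _calibrate_thresholds(
    mean_v: float, sd_v: float, k: int, r_target: float,
    lo: int, hi: int,
) -> tuple[np.ndarray, float]:
    """Solve discretisation thresholds and factor loading.

    Returns ``(boundaries, u)`` where an item takes value
    ``lo + sum(x > boundaries)`` for a standard-normal item latent ``x``
    and ``u`` is the squared factor loading. The loading satisfies
    ``u = (1 + (k-1) r) / (k * lam_d^2)`` with ``lam_d`` the linear
    attenuation of the thresholded item — the ``1/k`` structure absorbs
    the exact negative residual correlation of the sum-to-zero
    (permuted stratified quantile) residuals. Solved by a short fixed
    point since the thresholds depend on the loading and vice versa.
    """
    mu_item = mean_v / k
    if not lo < mu_item < hi:
        raise ValueError(
            f"target item mean {mu_item:.3f} outside response range ({lo}, {hi})")
    cuts = np.arange(lo, hi) + 0.5  # half-integer category boundaries
    lam_d2 = 1.0
    u = b = None
    for _ in range(8):
        # cap at 1 (shared latent, identical items) — the linear
        # attenuation model overstates the needed loading near r = 1,
        # where discretisation noise is common to the items, not
        # independent
        u = min((1.0 + (k - 1) * r_target) / (k * lam_d2), 1.0)
        width = max(sd_v / (k * np.sqrt(u)), 1e-6)

        def expected_mean(a: float) -> float:
            return lo + stats.norm.cdf((a - cuts) / width).sum() - mu_item

        span = max(10 * width, hi - lo + 10.0)
        a = optimize.brentq(expected_mean, lo - span, hi + span, xtol=1e-10)
        b = (cuts - a) / width
        upper = stats.norm.sf(b)  # P(x > b_j), decreasing in j
        probs = np.diff(np.concatenate(([1.0], upper, [0.0]))) * -1.0
        values = np.arange(lo, hi + 1, dtype=float)
        ev = probs @ values
        var_d = probs @ (values - ev) ** 2
        cov_xd = stats.norm.pdf(b).sum()  # unit value step per threshold
        new_lam = min(max(cov_xd**2 / max(var_d, 1e-12), 1e-4), 1.0)
        if abs(new_lam - lam_d2) < 1e-10:
            lam_d2 = new_lam
            break
        lam_d2 = new_lam
    return b, u


def disaggregate_to_items(
    scale_values: np.ndarray,
    n_items: int,
    target_alpha: float,
    item_range: tuple[int, int],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Integer item responses consistent with given scale scores.

    One-factor equicorrelated model with mean inter-item correlation
    ``r = alpha / (k - alpha (k-1))``; residuals are permuted stratified
    normal quantiles (sum-to-zero), so item sums correlate ~1 with the
    input scale values; discretisation to ``item_range`` uses
    normal-quantile thresholds placed so the expected item sum matches
    the input mean. Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v = np.asarray(scale_values, dtype=float)
    k = n_items
    lo, hi = item_range
    r_target = implied_interitem_r(target_alpha, k)
    mean_v = float(v.mean())
    sd_v = float(v.std(ddof=1))
    if sd_v <= 0:
        raise ValueError("scale values are constant; cannot disaggregate")
    z = (v - mean_v) / sd_v
    boundaries, u = _calibrate_thresholds(mean_v, sd_v, k, r_target, lo, hi)
    x = _latent_items(z, k, u, rng)
    return (lo + (x[:, :, None] > boundaries).sum(axis=2)).astype(int)


def _latent_items(z: np.ndarray, k: int, u: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Standard-normal item latents: loading sqrt(u) on z plus permuted
    stratified-quantile residuals (exact zero sum per participant)."""
    q = stats.norm.ppf((np.arange(k) + 0.5) / k)
    q = q - q.mean()
    q = q / np.sqrt(np.mean(q**2))
    perm = rng.random((len(z), k)).argsort(axis=1)
    return np.sqrt(u) * z[:, None] + np.sqrt(1.0 - u) * q[perm]


def _aq_raw_items(
    aq_latent: np.ndarray, alpha: float, rng: np.random.Generator,
    split_rng: np.random.Generator, keys: InstrumentKeys,
) -> np.ndarray:
    """Raw 1–4 AQ responses whose dichotomised (0/1) sum tracks the latent.

    The endorsement indicators are generated on the 0/1 scale (where the
    published alpha applies); the within-side split into the two adjacent
    response categories is uninformative for scoring and drawn 50/50.
    Agree-keyed items place endorsement at responses 1–2, disagree-keyed
    at 3–4.
    """
    endorsed = disaggregate_to_items(
        aq_latent, AQ_N_ITEMS, alpha, (0, 1), rng=rng)
    inner = split_rng.integers(0, 2, size=endorsed.shape)  # 0/1 sub-split
    agree_mask = np.array(
        [i in keys.aq_agree_keyed for i in range(1, AQ_N_ITEMS + 1)])
    raw = np.where(endorsed == 1, 1 + inner, 3 + inner)
    raw = np.where(agree_mask[None, :], raw, 5 - raw)
    return raw.astype(int)


def inject_missingness(
    items: np.ndarray,
    rate: float,
    max_missing_per_scale: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_ineligible: int = 0,
) -> np.ndarray:
    """Set item cells missing (NaN) independently at ``rate``.

    Rows exceeding ``max_missing_per_scale`` missing cells are truncated
    back to the cap (extra cells restored, earliest columns kept), except
    for ``n_ineligible`` randomly chosen rows which are forced to carry
    ``max_missing_per_scale + 1`` missing cells — handy for exercising
    downstream eligibility filtering.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.asarray(items, dtype=float).copy()
    n, k = out.shape
    forced = rng.choice(n, size=n_ineligible, replace=False) if n_ineligible else []
    if rate > 0:
        mask = rng.random(out.shape) < rate
        for i in range(n):
            hits = np.flatnonzero(mask[i])
            if len(hits) > max_missing_per_scale:
                mask[i, hits[max_missing_per_scale:]] = False
        out[mask] = np.nan
    for i in forced:
        cols = rng.choice(k, size=max_missing_per_scale + 1, replace=False)
        out[i, cols] = np.nan
    return out


def generate_cohort(
    specs: tuple[GroupSpec, GroupSpec] | list[GroupSpec],
    seed: int,
    keys: InstrumentKeys = DEFAULT_KEYS,
    max_missing_per_scale: int = 3,
    ineligible_per_group: int = 0,
) -> pd.DataFrame:
    """Full two-group item-level cohort (the CSV interchange schema).

    Composition of latent generation, item disaggregation per instrument
    and missingness injection (AQ and TAS items only; eligibility rules
    downstream count only those instruments). Round-trips losslessly
    through :func:`alexidom.io.write_cohort_csv` / ``read_cohort_csv``.
    """
    frames = []
    for g, spec in enumerate(specs):
        latent = generate_latent_cohort(spec, seed, group_index=g)

        raw_aq = _aq_raw_items(
            latent["aq"].to_numpy(), spec.alphas["aq"],
            stage_rng(seed, g, "aq"), stage_rng(seed, g, "rawsplit"), keys)

        # TAS: each subscale disaggregated against its own latent, then
        # assembled into the 20-item layout; reverse-keyed items are
        # stored as the raw response 6 - scored value.
        raw_tas = np.empty((spec.n, 20), dtype=int)
        sub_items = {"dif": keys.tas_dif, "ddf": keys.tas_ddf, "eot": keys.tas_eot}
        for name, (k_sub, rng_sub) in _TAS_SUBSCALES.items():
            scored = disaggregate_to_items(
                latent[name].to_numpy(), k_sub, spec.alphas[name], rng_sub,
                rng=stage_rng(seed, g, name))
            for col, item_no in enumerate(sub_items[name]):
                vals = scored[:, col]
                raw_tas[:, item_no - 1] = (
                    6 - vals if item_no in keys.tas_reverse else vals)

        raw_bdi = disaggregate_to_items(
            latent["bdi"].to_numpy(), 21, spec.alphas["bdi"], (0, 3),
            rng=stage_rng(seed, g, "bdi"))

        miss_rng = stage_rng(seed, g, "missing")
        aq_missing = inject_missingness(
            raw_aq, spec.missing_rate, max_missing_per_scale,
            rng=miss_rng, n_ineligible=ineligible_per_group)
        tas_missing = inject_missingness(
            raw_tas, spec.missing_rate, max_missing_per_scale, rng=miss_rng)

        frame = pd.DataFrame({
            "id": [f"{spec.group_label}-{g}{i:05d}" for i in range(spec.n)],
            "group": spec.group_label,
            "age": latent["age"].to_numpy(),
            "sex": latent["sex"].to_numpy(),
            "piq": latent["piq"].to_numpy(),
            "viq": latent["viq"].to_numpy(),
        })
        for j, col in enumerate(io.AQ_COLS):
            frame[col] = aq_missing[:, j]
        for j, col in enumerate(io.TAS_COLS):
            frame[col] = tas_missing[:, j]
        for j, col in enumerate(io.BDI_COLS):
            frame[col] = raw_bdi[:, j].astype(float)
        frames.append(frame)

    table = pd.concat(frames, ignore_index=True)
    for col in io.AQ_COLS + io.TAS_COLS + io.BDI_COLS:
        table[col] = table[col].astype("Int64") if table[col].isna().any() \
            else table[col].round().astype("Int64")
    io.validate_item_table(table)
    return table
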