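"""Synthetic protein-array cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be exercised without any real cohort download:

* log-scale positive intensities (raw values are 2**log2-model, so the
  floor-at-one rule is exercised by a tail of low noise values);
* two diagnosis classes with serum-cohort-like sizes (50 AD / 40 healthy
  discovery, 36 / 57 validation);
* planted *banded* markers — healthy values confined to an interval,
  AD values on one of the two flanks, the flank chosen by a latent
  severity variable shared across markers so that planted markers are
  strongly co-banded (a target inter-marker Pearson r, e.g. 0.99, is
  induced in closed form through the shared-flank mixture);
* optional one-sided (classical shift) markers;
* linear age and gender confounding on every feature;
* a large background of uninformative Gaussian noise features;
* a second cohort drawn from the same process with a location/scale
  distributional shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from .io_data import ExpressionDataset, TransformState


@dataclass(frozen=True)
class BandedMarker:
    """Geometry of one planted banded marker, in log2 units.

    Healthy values live inside ``healthy_center ± healthy_halfwidth``
    (truncated normal, sd = halfwidth/2, truncated at the band edges). AD
    values sit on the low or high flank at distance ``healthy_halfwidth +
    flank_gap`` from the center, spread by bounded within-flank noise of
    standard deviation ``within_class_sd`` (uniform on ±sqrt(3)·sd, drawn
    through a Gaussian copula so inter-marker correlations are exact in
    closed form). Because the noise is bounded, AD values are strictly
    outside the healthy band whenever ``flank_gap > sqrt(3)·within_class_sd``
    — true for the defaults, which makes a planted marker exactly separable.
    The flank is a latent variable shared across markers, low with
    probability ``flank_fraction_low``; ``loading_sign`` flips which latent
    flank maps to this marker's low side (a negative sign makes the marker
    anti-correlated with positively loaded ones).
    """

    healthy_center: float = 6.0
    healthy_halfwidth: float = 0.5
    flank_gap: float = 0.5
    flank_fraction_low: float = 0.5
    within_class_sd: float = 0.2
    loading_sign: int = 1

    def __post_init__(self) -> None:
        if self.healthy_halfwidth <= 0 or self.flank_gap <= 0:
            raise ValueError("halfwidth and flank_gap must be positive")
        if not 0 < self.flank_fraction_low < 1:
            raise ValueError("flank_fraction_low must be in (0, 1)")
        if self.loading_sign not in (-1, 1):
            raise ValueError("loading_sign must be ±1")

    @property
    def flank_offset(self) -> float:
        """Distance from the healthy center to an AD flank mode."""
        return self.healthy_halfwidth + self.flank_gap


@dataclass(frozen=True)
class OneSidedMarker:
    """Classical single-threshold marker: AD shifted by ``effect_size``."""

    center: float = 5.0
    effect_size: float = 1.5
    sd: float = 0.5


@dataclass(frozen=True)
class CohortShift:
    """Location/scale perturbation of the second cohort in log2 space:
    x' = center + scale * (x − center) + location, per feature, about the
    generating centers."""

    location: float = 0.25
    scale: float = 1.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the simulated cohorts.

    Defaults give a discovery cohort of 50 AD / 40 healthy with two
    co-banded planted markers (target AD-group Pearson r = 0.99) among 200
    noise features, mild age/gender confounding, and a shifted validation
    cohort of 36 AD / 57 healthy.
    """

    n_pos: int = 50
    n_neg: int = 40
    n_noise_features: int = 200
    banded_markers: tuple[BandedMarker, ...] = (BandedMarker(), BandedMarker())
    target_correlations: tuple[float, ...] = (0.99,)
    one_sided_markers: tuple[OneSidedMarker, ...] = ()
    age_range: tuple[float, float] = (60.0, 90.0)
    age_effect_sd: float = 0.003    # log2 units per year
    gender_effect_sd: float = 0.05  # log2 units
    noise_mean: float = 1.645       # log2; ~5% of raw noise values fall below 1
    noise_sd: float = 1.0
    val_n_pos: int = 36
    val_n_neg: int = 57
    cohort_shift: CohortShift = CohortShift()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("class sizes must be >= 2")
        k = len(self.banded_markers)
        if len(self.target_correlations) != k * (k - 1) // 2:
            raise ValueError("target_correlations must have one entry per marker pair "
                             "(upper triangle, row-major)")
        if any(abs(r) > 1 for r in self.target_correlations):
            raise ValueError("|target r| must be <= 1")

    @property
    def n_features(self) -> int:
        return len(self.banded_markers) + len(self.one_sided_markers) + self.n_noise_features

    @classmethod
    def three_marker(cls, **kwargs) -> "SyntheticSpec":
        """Preset with three co-banded markers and the pairwise AD-group
        correlation pattern (+0.99, −0.95, −0.94) of two positively and one
        negatively loaded marker."""
        # a wider gap and larger within-flank sd keep the weaker (|r| = 0.94)
        # target inside the feasible range of the flank-mixture model
        markers = (
            BandedMarker(loading_sign=1, flank_gap=0.75, within_class_sd=0.3),
            BandedMarker(loading_sign=1, flank_gap=0.75, within_class_sd=0.3),
            BandedMarker(loading_sign=-1, flank_gap=0.75, within_class_sd=0.3),
        )
        return cls(banded_markers=markers,
                   target_correlations=(0.99, -0.95, -0.94), **kwargs)


@dataclass
class GroundTruth:
    """What was planted: feature ids, generating parameters, and the latent
    flank assignment of each AD sample."""

    banded_ids: list[str]
    one_sided_ids: list[str]
    marker_params: list[dict]
    flank: pd.Series            # per AD sample id: 'low'/'high' latent flank
    expected_ad_correlation: pd.DataFrame

    @property
    def planted_feature_ids(self) -> list[str]:
        return self.banded_ids + self.one_sided_ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "banded_ids": self.banded_ids,
            "one_sided_ids": self.one_sided_ids,
            "marker_params": self.marker_params,
            "flank": self.flank.to_dict(),
            "expected_ad_correlation": self.expected_ad_correlation.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# closed-form correlation calibration
# ---------------------------------------------------------------------------

def _flank_cov(p_i: float, p_j: float) -> float:
    """Covariance of two ±1 flank indicators driven by one shared uniform."""
    lo, hi = min(p_i, p_j), max(p_i, p_j)
    return 4.0 * lo * (1.0 - hi)


def _solve_noise_correlation(spec: SyntheticSpec) -> np.ndarray:
    """Within-flank noise correlation matrix reproducing the target AD-group
    Pearson r under the two-point flank mixture. Raises if infeasible.

    The returned matrix is the correlation of the unit-variance bounded
    noise itself; :func:`_sample_banded_block` maps it to the latent
    Gaussian scale of the copula before sampling."""
    markers = spec.banded_markers
    k = len(markers)
    R = np.eye(k)
    # marker variance includes the (marker-independent) confounder variance,
    # so the calibration is unbiased for the observed, confounded values
    v_conf = (spec.age_effect_sd ** 2 * (spec.age_range[1] - spec.age_range[0]) ** 2 / 12
              + spec.gender_effect_sd ** 2 / 4)
    variances = [
        m.flank_offset ** 2 * _flank_cov(m.flank_fraction_low, m.flank_fraction_low)
        + m.within_class_sd ** 2 + v_conf
        for m in markers
    ]
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            mi, mj = markers[i], markers[j]
            target = spec.target_correlations[idx]
            idx += 1
            s = mi.loading_sign * mj.loading_sign
            num = (target * np.sqrt(variances[i] * variances[j]) / s
                   - mi.flank_offset * mj.flank_offset
                   * _flank_cov(mi.flank_fraction_low, mj.flank_fraction_low))
            rho = num / (mi.within_class_sd * mj.within_class_sd)
            if abs(rho) > 1:
                raise ValueError(
                    f"target r={target} between markers {i},{j} is infeasible "
                    f"(requires within-flank noise correlation {rho:.3f}); "
                    "targets refer to the observed values, so heavy age/gender "
                    "confounding or a large within-flank sd shrinks the "
                    "achievable range")
            R[i, j] = R[j, i] = rho
    try:
        np.linalg.cholesky(R + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError:
        raise ValueError("target correlations yield a non-positive-semidefinite "
                         "noise correlation matrix") from None
    return R


def expected_ad_correlation(spec: SyntheticSpec) -> pd.DataFrame:
    """The model's AD-group Pearson correlation matrix among banded markers
    (the generator is calibrated so this equals the targets)."""
    k = len(spec.banded_markers)
    out = np.eye(k)
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = spec.target_correlations[idx]
            idx += 1
    names = [f"BANDED{i + 1}" for i in range(k)]
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass
class _FeatureLayout:
    """Feature-level randomness shared by all blocks of one cohort (or all
    groups of a grouped cohort): column permutation and confounder slopes."""

    perm: np.ndarray
    age_coefs: np.ndarray
    gender_coefs: np.ndarray


def _draw_layout(spec: SyntheticSpec, rng: np.random.Generator) -> _FeatureLayout:
    k = spec.n_features
    return _FeatureLayout(
        perm=rng.permutation(k),
        age_coefs=rng.normal(0.0, spec.age_effect_sd, size=k),
        gender_coefs=rng.normal(0.0, spec.gender_effect_sd, size=k),
    )


def _sample_banded_block(
    spec: SyntheticSpec, n_pos: int, n_neg: int, rng: np.random.Generator,
    active: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Log2 values (AD block stacked over healthy block) for the banded
    markers, plus the latent flank (+1 high / −1 low) per AD sample. With
    ``active=False`` every sample is drawn from the healthy band (used for
    signal-free groups)."""
    markers = spec.banded_markers
    k = len(markers)
    if k == 0:
        return np.empty((n_pos + n_neg, 0)), np.ones(n_pos)
    R_eps = _solve_noise_correlation(spec)
    # latent Gaussian correlation of the copula whose uniform margins have
    # correlation R_eps:  rho_z = 2 sin(pi * rho_eps / 6)
    R_z = 2.0 * np.sin(np.pi * R_eps / 6.0)
    np.fill_diagonal(R_z, 1.0)
    try:
        L = np.linalg.cholesky(R_z + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError:
        raise ValueError("target correlations yield a non-positive-semidefinite "
                         "latent copula correlation matrix") from None

    def healthy_block(n: int) -> np.ndarray:
        cols = []
        for m in markers:
            sd = m.healthy_halfwidth / 2.0
            cols.append(m.healthy_center
                        + truncnorm.rvs(-2.0, 2.0, scale=sd, size=n, random_state=rng))
        return np.column_stack(cols)

    u = rng.uniform(size=n_pos)
    if not active:
        return np.vstack([healthy_block(n_pos), healthy_block(n_neg)]), np.ones(n_pos)

    z = rng.standard_normal(size=(n_pos, k)) @ L.T
    eps = np.sqrt(12.0) * (ndtr(z) - 0.5)  # uniform on ±sqrt(3): unit variance, bounded
    pos = np.empty((n_pos, k))
    d_shared = np.ones(n_pos)
    for j, m in enumerate(markers):
        d = np.where(u < m.flank_fraction_low, -1.0, 1.0)
        if j == 0:
            d_shared = d
        offset = d * m.flank_offset + m.within_class_sd * eps[:, j]
        pos[:, j] = m.healthy_center + m.loading_sign * offset
    return np.vstack([pos, healthy_block(n_neg)]), d_shared


def _assemble_cohort(
    spec: SyntheticSpec,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator,
    cohort_label: str,
    probe_prefix: str,
    layout: Optional[_FeatureLayout] = None,
    shift: Optional[CohortShift] = None,
    group_labels: Optional[Sequence[str]] = None,
    active: bool = True,
) -> tuple[ExpressionDataset, GroundTruth]:
    n = n_pos + n_neg
    k_b = len(spec.banded_markers)
    k_o = len(spec.one_sided_markers)
    k = spec.n_features
    if layout is None:
        layout = _draw_layout(spec, rng)

    banded, d_shared = _sample_banded_block(spec, n_pos, n_neg, rng, active=active)

    onesided_cols = []
    for m in spec.one_sided_markers:
        vals = rng.normal(m.center, m.sd, size=n)
        if active:
            vals[:n_pos] += m.effect_size
        onesided_cols.append(vals)
    onesided = np.column_stack(onesided_cols) if onesided_cols else np.empty((n, 0))

    noise = rng.normal(spec.noise_mean, spec.noise_sd, size=(n, spec.n_noise_features))
    log2 = np.hstack([banded, onesided, noise])

    centers = np.concatenate([
        [m.healthy_center for m in spec.banded_markers],
        [m.center for m in spec.one_sided_markers],
        np.full(spec.n_noise_features, spec.noise_mean),
    ])

    # age confounding is centered at the mid-cohort age so the planted marker
    # geometry stays at its configured location; the gender indicator uses
    # the same 0/1 coding as the correction model
    ages = np.round(rng.uniform(*spec.age_range, size=n), 1)
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    genders = np.array(["F", "M"])[rng.integers(0, 2, size=n)]
    log2 = (log2
            + np.outer(ages - mid_age, layout.age_coefs)
            + np.outer((genders == "M").astype(float), layout.gender_coefs))

    if shift is not None:
        log2 = centers + shift.scale * (log2 - centers) + shift.location

    perm = layout.perm
    log2 = log2[:, perm]
    genes = np.concatenate([
        [f"BANDED{i + 1}" for i in range(k_b)],
        [f"OSM{i + 1}" for i in range(k_o)],
        [f"NSE{i + 1:04d}" for i in range(spec.n_noise_features)],
    ])[perm]
    probe_ids = np.array([f"{probe_prefix}{i + 1:05d}" for i in range(k)])

    sample_ids = [f"{cohort_label}_S{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame({
        "diagnosis": np.array(["AD"] * n_pos + ["CONTROL"] * n_neg),
        "age": ages,
        "gender": genders,
        "cohort": cohort_label,
        "group": group_labels if group_labels is not None else np.nan,
    }, index=pd.Index(sample_ids, name="sample_id"))

    values = pd.DataFrame(np.power(2.0, log2), index=meta.index, columns=probe_ids)
    feature_meta = pd.DataFrame({"gene_symbol": genes},
                                index=pd.Index(probe_ids, name="feature_id"))
    ds = ExpressionDataset(values=values, sample_meta=meta, feature_meta=feature_meta,
                           transform_state=TransformState.RAW)

    gene_to_probe = dict(zip(genes, probe_ids))
    truth = GroundTruth(
        banded_ids=[gene_to_probe[f"BANDED{i + 1}"] for i in range(k_b)],
        one_sided_ids=[gene_to_probe[f"OSM{i + 1}"] for i in range(k_o)],
        marker_params=[asdict(m) for m in spec.banded_markers]
        + [asdict(m) for m in spec.one_sided_markers],
        flank=pd.Series(np.where(d_shared < 0, "low", "high"), index=sample_ids[:n_pos]),
        expected_ad_correlation=expected_ad_correlation(spec),
    )
    return ds, truth


def generate_cohort(spec: SyntheticSpec, seed: Optional[int] = None,
                    cohort_label: str = "discovery") -> tuple[ExpressionDataset, GroundTruth]:
    """Generate one raw-scale cohort plus its ground truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return _assemble_cohort(spec, spec.n_pos, spec.n_neg, rng,
                            cohort_label=cohort_label, probe_prefix="P")


def generate_cohort_pair(
    spec: SyntheticSpec, seed: Optional[int] = None,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Discovery cohort plus an independently drawn, distribution-shifted
    validation cohort (36 AD / 57 healthy by default). Features correspond
    across cohorts by gene symbol; probe ids differ, as across platforms.
    Because the shift is applied after sampling, identical seeds give
    common random numbers across shift settings."""
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    ss_disc, ss_val = ss.spawn(2)
    disc, truth = _assemble_cohort(
        spec, spec.n_pos, spec.n_neg, np.random.default_rng(ss_disc),
        cohort_label="discovery", probe_prefix="P")
    val, _ = _assemble_cohort(
        spec, spec.val_n_pos, spec.val_n_neg, np.random.default_rng(ss_val),
        cohort_label="validation", probe_prefix="Q", shift=spec.cohort_shift)
    return disc, val, truth


def generate_grouped_cohort(
    spec: SyntheticSpec,
    n_groups: int = 6,
    signal_groups: Sequence[int] = (0, 1),
    seed: Optional[int] = None,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Cohort split into per-group sample blocks (e.g. brain regions); the
    planted-marker effects are present only in ``signal_groups``, the noise
    structure and feature layout are shared. Class sizes are divided
    ~evenly across groups."""
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    signal_groups = sorted(set(signal_groups))
    if not signal_groups or min(signal_groups) < 0 or max(signal_groups) >= n_groups:
        raise ValueError("signal_groups must be a non-empty subset of range(n_groups)")
    pos_sizes = [len(a) for a in np.array_split(np.arange(spec.n_pos), n_groups)]
    neg_sizes = [len(a) for a in np.array_split(np.arange(spec.n_neg), n_groups)]
    if min(pos_sizes) < 2 or min(neg_sizes) < 2:
        raise ValueError("group sizes fall below 2 per class; increase n_pos/n_neg")

    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = ss.spawn(n_groups + 1)
    layout = _draw_layout(spec, np.random.default_rng(children[0]))
    parts = []
    truth0: Optional[GroundTruth] = None
    for g in range(n_groups):
        label = f"G{g + 1}"
        ds_g, truth_g = _assemble_cohort(
            spec, pos_sizes[g], neg_sizes[g], np.random.default_rng(children[g + 1]),
            cohort_label=f"grouped_{label}", probe_prefix="P", layout=layout,
            group_labels=[label] * (pos_sizes[g] + neg_sizes[g]),
            active=g in signal_groups,
        )
        if truth0 is None:
            truth0 = truth_g
        parts.append(ds_g)

    values = pd.concat([p.values for p in parts])
    meta = pd.concat([p.sample_meta for p in parts])
    meta["cohort"] = "grouped"
    ds = ExpressionDataset(values=values, sample_meta=meta,
                           feature_meta=parts[0].feature_meta,
                           transform_state=TransformState.RAW)
    assert truth0 is not None
    return ds, truth0
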