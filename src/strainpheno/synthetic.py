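"""Synthetic cohorts of regional longitudinal strain curves.

Generates carrier/control cohorts whose curve morphologies and covariate
distributions emulate a PLN-p.Arg14del-like disease model: controls with a
single systolic shortening peak, and four carrier phenotypes concentrated in
the apical/mid-septal and apical-lateral segments —

* **A** "diastolic notch": a small transient re-shortening bump during the
  early-diastolic upstroke, constrained so the global shortening peak stays
  at or before aortic valve closure (AVC);
* **B** "double peak": a second shortening peak after AVC forming a distinct
  local minimum;
* **C** "post-systolic shortening": the global peak shifted past AVC;
* **D** "reduced peak strain": peak-strain magnitude scaled down in every
  segment, most strongly apically.

Carriers labelled ``O_LIKE`` use the control template with carrier
covariates — pre-phenotypical variant carriers without disease features.
Every record stores its ground-truth phenotype so end-to-end recovery of the
phenotypes from trained-classifier relevance maps can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import (
    APICAL_SEGMENTS,
    CARRIER_PHENOTYPES,
    MODIFIER_SEGMENTS,
    PHENOTYPES,
    SEGMENTS,
    DeformationRecord,
)

_NOTCH_MARGIN_PCT = 0.5  # keep the post-AVC notch this far above the systolic peak


@dataclass
class CurveTemplateParams:
    """Morphology parameters of the strain-curve templates.

    ``peak_strain_pct`` is the positive magnitude S of maximal shortening
    (the curve's value at the peak is -S). Times are fractions of the RR
    interval. The bump amplitudes/positions are generator choices tuned to
    visually match the published representative curves; all configurable.
    """

    peak_strain_pct: float = 20.0
    peak_time_frac: float = 0.38
    avc_frac_true: float = 0.38
    notch_amp_pct: float = 2.0
    notch_time_frac: float = 0.55
    notch_width_frac: float = 0.08
    second_peak_amp_pct: float = 4.0
    second_peak_time_frac: float = 0.65
    second_peak_width_frac: float = 0.12
    pss_delay_frac: float = 0.12
    reduction_factor: float = 0.5        # phenotype D, apical segments
    reduction_factor_other: float = 0.7  # phenotype D, remaining segments
    noise_sd_pct: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_time_frac < 1.0):
            raise ValueError("peak_time_frac must lie in (0, 1)")
        if not (0.0 < self.avc_frac_true < 1.0):
            raise ValueError("avc_frac_true must lie in (0, 1)")
        if self.peak_strain_pct <= 0:
            raise ValueError("peak_strain_pct must be positive")
        for name in ("reduction_factor", "reduction_factor_other"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")
        for name in ("notch_width_frac", "second_peak_width_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroupCovariates:
    age_mean: float
    age_sd: float
    male_prob: float
    hr_mean: float
    hr_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.male_prob <= 1.0):
            raise ValueError("male_prob must lie in [0, 1]")
        for name in ("age_mean", "age_sd", "hr_mean", "hr_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.age_sd <= 0 or self.hr_sd <= 0:
            raise ValueError("distribution SDs must be positive")


@dataclass
class CovariateModel:
    """Per-group covariate distributions (age yrs, sex, heart rate bpm).

    Defaults reproduce the covariate imbalance of the disease cohort the
    generator emulates: carriers are younger and faster (HR ~ N(66.4, 11.1))
    than population controls (HR ~ N(58.5, 9.6)). Heart rate is clipped to
    the physiological support [35, 140] bpm.
    """

    control: GroupCovariates = field(
        default_factory=lambda: GroupCovariates(55.0, 13.5, 0.55, 58.5, 9.6)
    )
    carrier: GroupCovariates = field(
        default_factory=lambda: GroupCovariates(42.0, 14.0, 0.53, 66.4, 11.1)
    )

    def for_group(self, group: str) -> GroupCovariates:
        if group == "control":
            return self.control
        if group == "carrier":
            return self.carrier
        raise ValueError(f"unknown group {group!r}")


HR_SUPPORT = (35.0, 140.0)

#: Probability of a sustained-VA event during synthetic follow-up, by
#: phenotype; ordered like the published per-cluster event rates (cluster D
#: carries by far the worst prognosis, the feature-free cluster none).
EVENT_PROB = {"O_LIKE": 0.0, "A": 0.05, "B": 0.08, "C": 0.07, "D": 0.46}


def _raised_cosine(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Localized bump: 1 at `center`, 0 outside |t-center| >= half_width."""
    x = (t - center) / half_width
    out = np.where(np.abs(x) < 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return out


def _base_template(t: np.ndarray, S: float, t_p: float) -> np.ndarray:
    """Single-peak shortening/relengthening curve: 0 -> -S at t_p -> 0 at 1."""
    down = -S * (1.0 - np.cos(np.pi * t / t_p)) / 2.0
    up = -S * (1.0 + np.cos(np.pi * (t - t_p) / (1.0 - t_p))) / 2.0
    return np.where(t <= t_p, down, up)


def strain_template(
    phenotype: str,
    segment: str,
    params: CurveTemplateParams,
    t: np.ndarray,
) -> np.ndarray:
    """Noise-free strain template (%) for one segment on a time-fraction grid.

    Parameters
    ----------
    phenotype
        One of CONTROL, O_LIKE, A, B, C, D.
    segment
        Segment name from :data:`strainpheno.records.SEGMENTS`.
    params
        Morphology parameters; see :class:`CurveTemplateParams`.
    t
        Increasing grid of time fractions in [0, 1].

    Phenotype modifiers apply only to the mid-septal, apical-septal and
    apical-lateral segments, except D which reduces peak strain everywhere
    with the strongest reduction apically.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}; expected one of {SEGMENTS}")
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t must be an increasing 1-D grid")
    if t[0] < 0.0 or t[-1] > 1.0:
        raise ValueError("t must lie within [0, 1]")

    S = params.peak_strain_pct
    t_p = params.peak_time_frac
    in_modifier = segment in MODIFIER_SEGMENTS
    apical = segment in APICAL_SEGMENTS

    if phenotype == "D":
        factor = params.reduction_factor if apical else params.reduction_factor_other
        return _base_template(t, S * factor, t_p)

    if phenotype == "C" and in_modifier:
        return _base_template(t, S, params.avc_frac_true + params.pss_delay_frac)

    curve = _base_template(t, S, t_p)
    if phenotype in ("CONTROL", "O_LIKE", "C"):
        return curve

    if phenotype == "A" and in_modifier:
        notch = params.notch_amp_pct * _raised_cosine(
            t, params.notch_time_frac, params.notch_width_frac
        )
        avc = params.avc_frac_true
        # scale the notch so the global minimum stays at or before AVC;
        # the floor uses the unnotched systolic minimum (the notch can only
        # deepen the systolic side further, which keeps the guarantee)
        sys_min = curve[t <= avc].min() if np.any(t <= avc) else -S
        post = (t > avc) & (notch > 0)
        alpha = 1.0
        if np.any(post):
            floor = sys_min + _NOTCH_MARGIN_PCT
            allowed = (curve[post] - floor) / notch[post]
            alpha = float(np.clip(allowed.min(), 0.0, 1.0))
        return curve - alpha * notch

    if phenotype == "B" and in_modifier:
        bump = params.second_peak_amp_pct * _raised_cosine(
            t, params.second_peak_time_frac, params.second_peak_width_frac
        )
        return curve - bump

    return curve  # A/B outside their modifier segments


def _smoothed_noise(rng: np.random.Generator, shape: tuple, sd: float) -> np.ndarray:
    """Additive Gaussian noise smoothed with a 5-sample moving average.

    White noise is unphysiological for strain curves; the moving average
    mimics the smoothness of speckle-tracking output. The trace is pinned to
    zero at cycle onset (strain is measured relative to the onset length).
    """
    if sd == 0.0:
        return np.zeros(shape)
    e = rng.normal(0.0, sd, size=shape)
    kernel = np.ones(5) / 5.0
    e = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), -1, e)
    return e - e[..., :1]


def simulate_subject(
    group: str,
    phenotype: str,
    covariates: CovariateModel,
    seed: int,
    params: CurveTemplateParams | None = None,
    subject_id: str | None = None,
    echo_id: str = "e1",
    n_samples: int = 101,
    with_followup: bool = True,
) -> DeformationRecord:
    """Sample one subject: covariates, timing and noisy 6-segment curves.

    The same seed yields a bit-identical record. Carriers may carry any of
    O_LIKE/A/B/C/D; controls must carry CONTROL.
    """
    if group == "control" and phenotype != "CONTROL":
        raise ValueError(f"controls must have phenotype CONTROL, got {phenotype!r}")
    if group == "carrier" and phenotype not in CARRIER_PHENOTYPES:
        raise ValueError(
            f"carriers must have a phenotype in {CARRIER_PHENOTYPES}, got {phenotype!r}"
        )
    params = params or CurveTemplateParams()
    rng = np.random.default_rng(seed)
    gc = covariates.for_group(group)

    age = float(np.clip(rng.normal(gc.age_mean, gc.age_sd), 18.0, 90.0))
    sex = "male" if rng.random() < gc.male_prob else "female"
    hr = float(np.clip(rng.normal(gc.hr_mean, gc.hr_sd), *HR_SUPPORT))
    rr = 60000.0 / hr

    # per-subject morphology variation around the template defaults
    avc_frac = float(np.clip(rng.normal(params.avc_frac_true, 0.02), 0.30, 0.46))
    peak_time = float(np.clip(avc_frac - abs(rng.normal(0.0, 0.01)), 0.25, avc_frac))
    S_subject = float(np.clip(rng.normal(params.peak_strain_pct, 1.5), 10.0, 30.0))
    subject_params = replace(
        params,
        peak_strain_pct=S_subject,
        peak_time_frac=peak_time,
        avc_frac_true=avc_frac,
    )

    t = np.linspace(0.0, 1.0, n_samples)
    seg_jitter = rng.normal(0.0, 0.75, size=len(SEGMENTS))
    rows = []
    for seg, jit in zip(SEGMENTS, seg_jitter):
        p_seg = replace(
            subject_params,
            peak_strain_pct=float(np.clip(subject_params.peak_strain_pct + jit, 8.0, 32.0)),
        )
        rows.append(strain_template(phenotype, seg, p_seg, t))
    curves = np.vstack(rows) + _smoothed_noise(rng, (len(SEGMENTS), n_samples), params.noise_sd_pct)

    followup_years = None
    event = None
    if with_followup and group == "carrier":
        total = float(rng.uniform(0.5, 6.0))
        if rng.random() < EVENT_PROB[phenotype]:
            event = True
            followup_years = float(total * rng.uniform(0.2, 1.0))
        else:
            event = False
            followup_years = total

    return DeformationRecord(
        subject_id=subject_id or f"{group[:3].upper()}-{seed}",
        echo_id=echo_id,
        group=group,
        phenotype_truth=phenotype,
        age=age,
        sex=sex,
        heart_rate=hr,
        rr_interval=rr,
        avc_time=avc_frac * rr,
        curves=curves,
        followup_years=followup_years,
        event_sustained_va=event,
    )


def simulate_cohort(
    n_carriers: int,
    n_controls: int,
    phenotype_mix: dict[str, float] | None = None,
    covariates: CovariateModel | None = None,
    seed: int = 0,
    params: CurveTemplateParams | None = None,
    n_samples: int = 101,
) -> list[DeformationRecord]:
    """Simulate a full cohort of carrier and control records.

    ``phenotype_mix`` gives proportions over the carrier phenotypes
    {O_LIKE, A, B, C, D}; realized counts are a single multinomial draw
    under ``seed``. Defaults to the uniform mix.
    """
    if n_carriers < 0 or n_controls < 0:
        raise ValueError("counts must be non-negative")
    if phenotype_mix is None:
        phenotype_mix = {p: 1.0 / len(CARRIER_PHENOTYPES) for p in CARRIER_PHENOTYPES}
    unknown = set(phenotype_mix) - set(CARRIER_PHENOTYPES)
    if unknown:
        raise ValueError(f"phenotype_mix contains non-carrier phenotypes: {sorted(unknown)}")
    probs = np.array([phenotype_mix.get(p, 0.0) for p in CARRIER_PHENOTYPES])
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("phenotype_mix proportions must be >= 0 and sum to 1")
    covariates = covariates or CovariateModel()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_carriers, probs)
    phenotypes: list[str] = []
    for pheno, c in zip(CARRIER_PHENOTYPES, counts):
        phenotypes.extend([pheno] * int(c))

    records: list[DeformationRecord] = []
    carrier_seeds = rng.integers(0, 2**31, size=n_carriers)
    for i, (pheno, s) in enumerate(zip(phenotypes, carrier_seeds)):
        records.append(
            simulate_subject(
                "carrier", pheno, covariates, int(s), params=params,
                subject_id=f"CAR{i + 1:04d}", n_samples=n_samples,
            )
        )
    control_seeds = rng.integers(0, 2**31, size=n_controls)
    for i, s in enumerate(control_seeds):
        records.append(
            simulate_subject(
                "control", "CONTROL", covariates, int(s), params=params,
                subject_id=f"CON{i + 1:04d}", n_samples=n_samples,
            )
        )
    return records
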