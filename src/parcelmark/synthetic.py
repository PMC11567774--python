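"""Synthetic cohort generator.

Produces case/control cohorts with the statistical structure the
downstream pipeline assumes: per-parcel Gaussian structural measures with
planted group mean shifts of configurable Cohen's d, a latent-factor
model for cortical thickness whose inter-regional (structural-covariance)
correlation can be raised in cases, a smaller intracranial volume in
cases with cortical surface area generated independently of that shift,
hub-structured resting-state connectomes that can be "flattened" in
cases, and additive/multiplicative batch (site) effects applied last.

All randomness flows from a single integer seed; identical configs and
seeds yield byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from parcelmark.core import (
    SUBCORTICAL_LABELS,
    FeatureMatrix,
    ParcellatedSample,
    RestingTimeseries,
    parcel_labels,
)

STRUCTURAL_MEASURES = ("area", "thickness", "myelin", "subcortical", "etiv")

#: Default residual noise per measure. Area and subcortical volumes use a
#: fractional SD (relative to the parcel/structure template mean, since
#: structure sizes span orders of magnitude); thickness (mm), myelin
#: (ratio) and eTIV (mm^3) use absolute SDs on physiological scales.
DEFAULT_NOISE_SD: dict[str, float] = {
    "area": 0.10,
    "thickness": 0.12,
    "myelin": 0.10,
    "subcortical": 0.12,
    "etiv": 130_000.0,
}

#: Baseline inter-regional (across-subject) correlation of cortical
#: thickness in controls; structural covariance of thickness is
#: consistently positive in adult cohorts.
BASE_THICKNESS_COUPLING = 0.30

#: Fraction of parcels acting as connectome hubs and the factor by which
#: hub edges are strengthened in the control template.
HUB_FRACTION = 0.10
HUB_BOOST = 2.0

_TEMPLATE_SEED = 20_240_360  # population templates are config-independent


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the reference study design: 102 cases scanned at a
    single local site (batch 1) and four control batches of 25, 25, 300
    and 300 subjects (local, local with the alternative protocol, and two
    large external repositories), i.e. 650 controls in total.

    Parameters
    ----------
    effect_map
        Per-measure list of ``(parcel_indices, cohens_d)`` planted group
        mean shifts: case mean = control mean + d * SD on the listed
        parcels. Keys are measure names (``area``, ``thickness``,
        ``myelin``, ``subcortical``).
    etiv_effect_d
        Standardized shift of intracranial volume in cases (negative for
        smaller heads). Cortical surface area is generated independently
        of this shift, so area-per-volume rises when it is negative.
    coupling_boost
        Increment to the inter-regional thickness correlation in cases
        (added to the control baseline of 0.30).
    hub_flattening
        Strength in [0, 1] shrinking case connectome hub weights toward
        the mean edge weight (0 = identical templates, 1 = fully flat).
    batch_shift, batch_scale
        Per-measure sequences of one additive offset (in units of the
        measure's residual SD) / one multiplicative residual scale per
        batch. Scales must be positive.
    noise_sd
        Overrides of the per-measure residual SDs.
    effect_scales_with_types
        When True, each case's planted structural shift is multiplied by
        ``n_types / mean(n_types)``, tying effect size to the number of
        reported trait types.
    """

    n_cases: int = 102
    n_controls_per_batch: Sequence[int] = (25, 25, 300, 300)
    n_parcels: int = 360
    n_subcortical: int = 34
    n_timepoints: int = 300
    effect_map: Mapping[str, Sequence[tuple[Sequence[int], float]]] = field(
        default_factory=dict
    )
    etiv_effect_d: float = 0.0
    coupling_boost: float = 0.0
    hub_flattening: float = 0.0
    batch_shift: Mapping[str, Sequence[float]] | None = None
    batch_scale: Mapping[str, Sequence[float]] | None = None
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    sex_ratio_f: float = 0.75
    effect_scales_with_types: bool = False
    include_timeseries: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_cases, self.n_parcels, self.n_subcortical, self.n_timepoints]
        counts += list(self.n_controls_per_batch)
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all cohort counts must be positive")
        if not 0.0 <= self.hub_flattening <= 1.0:
            raise ValueError("hub_flattening must lie in [0, 1]")
        sd = dict(DEFAULT_NOISE_SD)
        sd.update(self.noise_sd)
        if any(v <= 0 for v in sd.values()):
            raise ValueError("noise_sd must be positive for every measure")
        self.noise_sd = sd
        for measure, entries in self.effect_map.items():
            if measure not in ("area", "thickness", "myelin", "subcortical"):
                raise ValueError(f"unknown measure in effect_map: {measure!r}")
            limit = self.n_subcortical if measure == "subcortical" else self.n_parcels
            for idx, _d in entries:
                if np.any(np.asarray(idx) >= limit) or np.any(np.asarray(idx) < 0):
                    raise ValueError(f"effect parcel index out of range for {measure}")
        n_batches = len(self.n_controls_per_batch)
        for name, table in (("batch_shift", self.batch_shift), ("batch_scale", self.batch_scale)):
            if table is None:
                continue
            for measure, values in table.items():
                if measure not in STRUCTURAL_MEASURES:
                    raise ValueError(f"unknown measure in {name}: {measure!r}")
                if len(values) != n_batches:
                    raise ValueError(f"{name}[{measure!r}] must list one value per batch")
        if self.batch_scale is not None:
            for values in self.batch_scale.values():
                if np.any(np.asarray(values, dtype=float) <= 0):
                    raise ValueError("batch_scale values must be positive")

    @property
    def n_batches(self) -> int:
        return len(self.n_controls_per_batch)

    @property
    def n_controls(self) -> int:
        return int(sum(self.n_controls_per_batch))


def _templates(config: CohortConfig) -> dict[str, np.ndarray]:
    """Population mean templates, independent of the cohort seed."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    p, s = config.n_parcels, config.n_subcortical
    area_mu = np.exp(rng.normal(np.log(480.0), 0.35, size=p))  # mm^2 per parcel
    thick_mu = np.clip(rng.normal(2.6, 0.20, size=p), 1.8, 3.6)  # mm
    myelin_mu = np.clip(rng.normal(1.50, 0.15, size=p), 0.9, 2.2)  # ratio
    subcort_mu = np.exp(rng.normal(np.log(3000.0), 1.0, size=s))  # mm^3
    return {
        "area": area_mu,
        "thickness": thick_mu,
        "myelin": myelin_mu,
        "subcortical": subcort_mu,
        "etiv": np.array([1_500_000.0]),
    }


def _measure_sd(config: CohortConfig, templates: dict[str, np.ndarray], measure: str) -> np.ndarray:
    """Residual SD vector for one measure (fractional for sizes)."""
    if measure in ("area", "subcortical"):
        return config.noise_sd[measure] * templates[measure]
    if measure == "etiv":
        return np.array([config.noise_sd["etiv"]])
    return np.full(templates[measure].shape, config.noise_sd[measure])


def hub_indices(n_parcels: int) -> np.ndarray:
    """Parcels acting as connectome hubs (spread uniformly across blocks)."""
    step = max(1, round(1.0 / HUB_FRACTION))
    return np.arange(0, n_parcels, step)


def connectome_template(n_parcels: int, hub_flattening: float = 0.0) -> np.ndarray:
    """Group-level connectome correlation template.

    A 5-block stochastic-block structure (within-block coupling 0.3,
    between-block 0.05) with 10% hub parcels whose edges are doubled.
    ``hub_flattening`` shrinks every off-diagonal entry toward the mean
    edge weight, removing the hub/spoke asymmetry. The result is
    eigenvalue-floored and renormalized to a valid correlation matrix.
    """
    n_blocks = 5
    block = np.repeat(np.arange(n_blocks), int(np.ceil(n_parcels / n_blocks)))[:n_parcels]
    same = block[:, None] == block[None, :]
    w = np.where(same, 0.30, 0.05)
    hubs = hub_indices(n_parcels)
    hub_mask = np.zeros(n_parcels, dtype=bool)
    hub_mask[hubs] = True
    boost = np.where(hub_mask[:, None] | hub_mask[None, :], HUB_BOOST, 1.0)
    w = np.minimum(w * boost, 0.8)
    np.fill_diagonal(w, 1.0)
    if hub_flattening > 0.0:
        off = ~np.eye(n_parcels, dtype=bool)
        mean_w = w[off].mean()
        w[off] = (1.0 - hub_flattening) * w[off] + hub_flattening * mean_w
    # eigenvalue floor, then renormalize to unit diagonal
    vals, vecs = np.linalg.eigh(w)
    vals = np.maximum(vals, 1e-3)
    w = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(w))
    w = w / np.outer(d, d)
    np.fill_diagonal(w, 1.0)
    return w


def _case_shift(config: CohortConfig, templates: dict[str, np.ndarray], measure: str) -> np.ndarray:
    """Planted case-minus-control mean shift for one structural measure."""
    sd = _measure_sd(config, templates, measure)
    shift = np.zeros_like(templates[measure])
    for idx, d in config.effect_map.get(measure, ()):  # case mean = control + d*SD
        idx = np.asarray(idx, dtype=int)
        shift[idx] += d * sd[idx]
    return shift


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ParcellatedSample], list[RestingTimeseries]]:
    """Generate a full synthetic cohort.

    Returns the structural samples (cases first, then controls grouped by
    batch) and, when ``config.include_timeseries`` is set, one resting
    time series per subject in the same order.

    Structural measures are per-parcel Gaussians; thickness follows a
    one-factor model giving inter-regional correlation 0.30 in controls
    and ``0.30 + coupling_boost`` in cases; eTIV is shifted by
    ``etiv_effect_d`` while total surface area is the (independent) sum
    of parcel areas; time series are drawn from hub-structured group
    connectome templates with case templates flattened by
    ``hub_flattening``; batch location/scale effects are applied last.
    """
    rng = np.random.default_rng(config.seed)
    templates = _templates(config)
    p = config.n_parcels

    groups = ["case"] * config.n_cases
    batches = [1] * config.n_cases
    for b, n_b in enumerate(config.n_controls_per_batch, start=1):
        groups += ["control"] * n_b
        batches += [b] * n_b
    n_total = len(groups)

    sexes = np.where(rng.random(n_total) < config.sex_ratio_f, "F", "M")
    ages = rng.uniform(18.0, 65.0, size=n_total)
    n_types = np.zeros(n_total, dtype=int)
    n_types[: config.n_cases] = sample_n_types(config.n_cases, rng)

    if config.effect_scales_with_types:
        type_factor = np.ones(n_total)
        mean_types = n_types[: config.n_cases].mean()
        type_factor[: config.n_cases] = n_types[: config.n_cases] / mean_types
    else:
        type_factor = np.ones(n_total)

    shifts = {m: _case_shift(config, templates, m) for m in ("area", "thickness", "myelin", "subcortical")}
    is_case = np.asarray([g == "case" for g in groups])

    # --- structural measures ------------------------------------------------
    values: dict[str, np.ndarray] = {}
    for measure in ("area", "myelin", "subcortical"):
        mu = templates[measure]
        sd = _measure_sd(config, templates, measure)
        x = mu + sd * rng.standard_normal((n_total, mu.size))
        x[is_case] += type_factor[is_case, None] * shifts[measure]
        values[measure] = x

    # thickness: one latent factor per subject sets the inter-regional
    # across-subject correlation; cases get a stronger loading
    sd_t = _measure_sd(config, templates, "thickness")
    rho = np.where(is_case, min(0.95, BASE_THICKNESS_COUPLING + config.coupling_boost),
                   BASE_THICKNESS_COUPLING)
    factor = rng.standard_normal(n_total)
    eps = rng.standard_normal((n_total, p))
    thick = (templates["thickness"]
             + sd_t * (np.sqrt(rho)[:, None] * factor[:, None]
                       + np.sqrt(1.0 - rho)[:, None] * eps))
    thick[is_case] += type_factor[is_case, None] * shifts["thickness"]
    values["thickness"] = thick

    etiv = (templates["etiv"][0]
            + config.noise_sd["etiv"] * rng.standard_normal(n_total))
    etiv[is_case] += config.etiv_effect_d * config.noise_sd["etiv"]

    # --- batch location/scale effects (applied last, residual-centered) ----
    batch_arr = np.asarray(batches)
    for measure in STRUCTURAL_MEASURES:
        shift_tab = (config.batch_shift or {}).get(measure)
        scale_tab = (config.batch_scale or {}).get(measure)
        if shift_tab is None and scale_tab is None:
            continue
        mu = templates[measure] if measure != "etiv" else templates["etiv"]
        sd = _measure_sd(config, templates, measure)
        target = etiv[:, None] if measure == "etiv" else values[measure]
        for b in range(1, config.n_batches + 1):
            rows = batch_arr == b
            scale = 1.0 if scale_tab is None else float(scale_tab[b - 1])
            shift = 0.0 if shift_tab is None else float(shift_tab[b - 1])
            target[rows] = mu + scale * (target[rows] - mu) + shift * sd
        if measure == "etiv":
            etiv = target[:, 0]

    # --- assemble samples ---------------------------------------------------
    labels = parcel_labels(p)  # noqa: F841  (fixed ordering; used by io)
    samples: list[ParcellatedSample] = []
    case_i = ctrl_i = 0
    for i in range(n_total):
        if groups[i] == "case":
            case_i += 1
            sid = f"case{case_i:03d}"
        else:
            ctrl_i += 1
            sid = f"ctrl{ctrl_i:03d}"
        area_i = np.maximum(values["area"][i], 1.0)
        samples.append(
            ParcellatedSample(
                subject_id=sid,
                group=groups[i],
                batch=batches[i],
                sex=str(sexes[i]),
                age=float(ages[i]),
                n_types=int(n_types[i]),
                area=area_i,
                thickness=values["thickness"][i],
                myelin=values["myelin"][i],
                subcortical=np.maximum(values["subcortical"][i], 1.0),
                etiv=float(max(etiv[i], 1.0)),
                global_area=float(area_i.sum()),
            )
        )

    # --- resting-state time series ------------------------------------------
    timeseries: list[RestingTimeseries] = []
    if config.include_timeseries:
        t = max(config.n_timepoints, -(-p // 4))  # generator guarantee T >= p/4
        chol = {
            False: np.linalg.cholesky(connectome_template(p, 0.0)),
            True: np.linalg.cholesky(connectome_template(p, config.hub_flattening)),
        }
        obs_noise = 0.5
        for i, s in enumerate(samples):
            z = chol[bool(is_case[i])] @ rng.standard_normal((p, t))
            z += obs_noise * rng.standard_normal((p, t))
            timeseries.append(RestingTimeseries(subject_id=s.subject_id, data=z))

    return samples, timeseries


def sample_n_types(n: int, rng: np.random.Generator) -> np.ndarray:
    """Zipf-like number of trait types per case over 1..8 (many 1-type)."""
    k = np.arange(1, 9)
    w = k ** -1.2
    return rng.choice(k, size=n, p=w / w.sum())


#: The 35 behavioral dependent variables, grouped as in the reference
#: battery: autistic traits (5), sensory sensitivity (1), anxiety
#: sensitivity (3), mental health (3), post-traumatic stress (3),
#: hypermobility (1), personality (5), creativity (2), memory (4), fluid
#: intelligence (1), sensory imagery (7).
BEHAVIORAL_VARIABLES: tuple[str, ...] = (
    "AQ_social_skills", "AQ_imagination", "AQ_communication",
    "AQ_attention_detail", "AQ_attention_switching",
    "GSQ_sensory",
    "ASI_social", "ASI_physical", "ASI_cognitive",
    "DASS_depression", "DASS_stress", "DASS_anxiety",
    "IES_intrusions", "IES_hyperarousal", "IES_avoidance",
    "hypermobility",
    "BFI_openness", "BFI_negative_emotion", "BFI_conscientiousness",
    "BFI_agreeableness", "BFI_extraversion",
    "AUT_creativity", "AUT_novelty",
    "MEM_acc_conf", "MEM_auc", "MEM_familiarity", "MEM_recollection",
    "ravens_matrices",
    "IMG_smell", "IMG_vision", "IMG_touch", "IMG_taste",
    "IMG_sound", "IMG_emotion", "IMG_body",
)


def behavioral_table(
    n_cases: int = 128,
    n_controls: int = 109,
    effects: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, pd.Series]:
    """Generate the 35-variable behavioral table with planted shifts.

    Variables are independent standard Gaussians; cases are shifted by
    the per-variable Cohen's d in ``effects`` (zeros when omitted).
    Returns a :class:`FeatureMatrix` and a group-label Series
    (``case``/``control``) indexed by subject id.
    """
    if effects is None:
        effects = np.zeros(len(BEHAVIORAL_VARIABLES))
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (len(BEHAVIORAL_VARIABLES),):
        raise ValueError(f"effects must have length {len(BEHAVIORAL_VARIABLES)}")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    x = rng.standard_normal((n, effects.size))
    x[:n_cases] += effects
    ids = [f"case{i + 1:03d}" for i in range(n_cases)] + [
        f"ctrl{i + 1:03d}" for i in range(n_controls)
    ]
    labels = pd.Series(["case"] * n_cases + ["control"] * n_controls,
                       index=ids, name="group")
    fm = FeatureMatrix(
        biomarker_id="behavioral",
        values=x,
        feature_names=list(BEHAVIORAL_VARIABLES),
        subject_ids=ids,
    )
    return fm, labels
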