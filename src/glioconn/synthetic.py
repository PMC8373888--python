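"""Synthetic multimodal cohort generator.

Produces complete per-subject derivatives — streamline-count matrices, FA
edge matrices, ROI time series and demographics — for a three-group cohort
(healthy controls and two glioma groups split by IDH-mutation status), with
plantable group effects and within-modality coherence.

Generative model
----------------
Each subject carries a 3 x 3 grid of latent *compartment targets*
``v[modality, compartment]`` (modalities EW, FA, FC; compartments left,
right, interhemispheric):

    v = mu[mod, comp] + delta[group, lesion side] +
        scale[mod, comp] * (lambda[group, mod] * g_mod + resid_sd * eta)

where ``g_mod`` is a per-subject standard-normal coherence factor shared by
the three compartments of one modality (independent across modalities, so
intermodal correlations are null by construction), ``eta`` is independent
compartment noise, and ``lambda`` is the coherence loading.  Group effects
``delta`` plant the study-type findings: reduced interhemispheric edge
weight in both patient groups, an ipsilesional FA decrease in IDHwt and a
contralesional FA increase in IDHmut.

Edge-level data are then realized to match the targets:

* counts — Poisson draws on a fixed sparse edge template (dense within
  hemispheres, sparse between) plus a diffuse low-rate background field.
  Because the edge-weight normalization is scale-invariant, block rate
  scales alone cannot move the intrahemispheric EW level; the background
  field inflates region strengths (denominators) without ever surviving the
  all-controls edge mask, giving a fourth calibration dial.  Block scales
  and background strength are solved per subject by damped fixed-point
  iteration so the *expected* compartment EW means equal the targets.
* FA — truncated-normal noise around the compartment target on every edge
  with at least one streamline, missing elsewhere.
* time series — T draws from a zero-mean Gaussian factor model whose
  implied block correlation structure (within-left, within-right, between)
  matches the tanh of the target Fisher-z values exactly.

A single master seed deterministically spawns per-subject substreams, so
cohorts are bit-reproducible and subjects independent.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import FAEdgeMatrix, RoiTimeSeries, StreamlineCountMatrix
from .parcellation import (CODE_INTER, CODE_INTRA_LEFT, CODE_INTRA_RIGHT,
                           AtlasDefinition, compartment_codes, default_atlas,
                           make_atlas)
from .summarize import SubjectRecord

logger = logging.getLogger(__name__)

MODALITIES = ("EW", "FA", "FC")
COMPARTMENTS = ("left", "right", "inter")
GROUPS = ("control", "IDHmut", "IDHwt")

_CODE_BY_COMPARTMENT = {"left": CODE_INTRA_LEFT, "right": CODE_INTRA_RIGHT,
                        "inter": CODE_INTER}


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations or targets."""


def _default_baselines():
    return {
        ("EW", "left"): 0.06, ("EW", "right"): 0.06, ("EW", "inter"): 0.02,
        ("FA", "left"): 0.45, ("FA", "right"): 0.45, ("FA", "inter"): 0.48,
        ("FC", "left"): 0.35, ("FC", "right"): 0.35, ("FC", "inter"): 0.25,
    }


def _default_scales():
    return {
        ("EW", "left"): 0.006, ("EW", "right"): 0.006, ("EW", "inter"): 0.004,
        ("FA", "left"): 0.02, ("FA", "right"): 0.02, ("FA", "inter"): 0.02,
        ("FC", "left"): 0.06, ("FC", "right"): 0.06, ("FC", "inter"): 0.06,
    }


def _default_loadings():
    return {
        "control": {"EW": 0.8, "FA": 0.8, "FC": 0.8},
        "IDHmut": {"EW": 0.0, "FA": 0.0, "FC": 0.8},
        "IDHwt": {"EW": 0.0, "FA": 0.0, "FC": 0.8},
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Group sizes, age distributions, sex ratios and lesion-side frequencies
    follow the study cohort (27 controls, 15 IDHmut, 14 IDHwt); effect sizes
    default to an interhemispheric EW reduction of 15% of baseline in both
    patient groups, an ipsilesional FA decrease of 0.03 in IDHwt and a
    contralesional FA increase of 0.03 in IDHmut.  Coherence loadings default
    to 0.8 on all modalities for controls and to 0 on the structural
    modalities (EW, FA) for patients, which plants the structural/functional
    coherence dissociation.
    """

    n_regions: int = 246
    n_timepoints: int = 300
    group_sizes: dict = field(default_factory=lambda: {
        "control": 27, "IDHmut": 15, "IDHwt": 14})
    age_params: dict = field(default_factory=lambda: {
        "control": (46.0, 14.0), "IDHmut": (37.0, 11.0), "IDHwt": (65.0, 8.0)})
    age_bounds: tuple = (18.0, 80.0)
    lesion_left_prob: dict = field(default_factory=lambda: {
        "IDHmut": 10 / 15, "IDHwt": 9 / 14})
    male_prob: dict = field(default_factory=lambda: {
        "control": 17 / 27, "IDHmut": 11 / 15, "IDHwt": 6 / 14})
    baseline_means: dict = field(default_factory=_default_baselines)
    subject_scale: dict = field(default_factory=_default_scales)
    delta_ew_inter_patients: float = -0.003   # -15% of the 0.02 baseline
    delta_fa_ipsi_idhwt: float = -0.03
    delta_fa_contra_idhmut: float = +0.03
    loadings: dict = field(default_factory=_default_loadings)
    resid_sd: float = 0.15
    n_edges: dict = field(default_factory=lambda: {
        "intra_left": 619, "intra_right": 637, "inter": 92})
    rate_range_intra: tuple = (15.0, 45.0)
    rate_range_inter: tuple = (45.0, 75.0)
    fa_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_regions < 8 or self.n_regions % 2:
            raise SimulationError("n_regions must be an even integer >= 8")
        if self.n_timepoints < 3:
            raise SimulationError("n_timepoints must be >= 3")
        for group in GROUPS:
            if self.group_sizes.get(group, 0) < 4:
                raise SimulationError(f"group {group!r} needs >= 4 subjects")
        for prob_map in (self.lesion_left_prob, self.male_prob):
            for key, p in prob_map.items():
                if not 0.0 <= p <= 1.0:
                    raise SimulationError(
                        f"probability {key!r}={p} outside [0, 1]")
        for (mod, comp), mu in self.baseline_means.items():
            if mod in ("EW", "FA") and not 0.0 < mu < 1.0:
                raise SimulationError(
                    f"baseline {mod}/{comp}={mu} outside (0, 1)")
        for key, s in self.subject_scale.items():
            if s <= 0:
                raise SimulationError(f"subject scale {key} must be > 0")
        if self.resid_sd <= 0:
            raise SimulationError("resid_sd must be > 0")
        for key, rng in (("intra", self.rate_range_intra),
                         ("inter", self.rate_range_inter)):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise SimulationError(f"invalid {key} rate range {rng}")
        half = self.n_regions // 2
        max_intra = half * (half - 1) // 2
        if (self.n_edges["intra_left"] > max_intra
                or self.n_edges["intra_right"] > max_intra
                or self.n_edges["inter"] > half * half):
            raise SimulationError("edge template larger than available pairs")
        # FA targets must stay inside (0, 1) under the planted effects
        for comp in COMPARTMENTS:
            base = self.baseline_means[("FA", comp)]
            for delta in (self.delta_fa_ipsi_idhwt, self.delta_fa_contra_idhmut):
                if not 0.0 < base + delta < 1.0:
                    raise SimulationError("FA effect pushes target outside "
                                          "(0, 1)")

    @classmethod
    def reduced(cls, **overrides) -> "SimulationConfig":
        """Reduced-size conditions for fast simulation suites.

        40 regions, 120 time points and a proportionally thinned edge
        template.  The edge-weight baselines (and with them the
        interhemispheric effect, kept at -15% of baseline) are raised to
        match the denser effective graph of the small parcellation: with
        ~20 regions per hemisphere the per-edge normalized weight is
        intrinsically larger, and keeping the 246-region baselines would
        require a diffuse background field strong enough to leak into the
        control edge mask.
        """
        defaults = dict(
            n_regions=40, n_timepoints=120,
            n_edges={"intra_left": 60, "intra_right": 62, "inter": 20},
            baseline_means={**_default_baselines(),
                            ("EW", "left"): 0.12, ("EW", "right"): 0.12,
                            ("EW", "inter"): 0.04},
            subject_scale={**_default_scales(),
                           ("EW", "left"): 0.006, ("EW", "right"): 0.006,
                           ("EW", "inter"): 0.003},
            delta_ew_inter_patients=-0.006,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def null_variant(self) -> "SimulationConfig":
        """No planted effects and equal coherence loadings in every group."""
        cfg = replace(self, delta_ew_inter_patients=0.0,
                      delta_fa_ipsi_idhwt=0.0, delta_fa_contra_idhmut=0.0)
        cfg.loadings = {g: {"EW": 0.8, "FA": 0.8, "FC": 0.8} for g in GROUPS}
        return cfg


@dataclass(frozen=True)
class EdgeTemplate:
    """Fixed cohort-level edge topology and base streamline rates."""

    n_regions: int
    edge_i: np.ndarray          # first region index per template edge
    edge_j: np.ndarray          # second region index (i < j)
    edge_rate: np.ndarray       # base Poisson rate per edge
    edge_comp: np.ndarray       # compartment code per edge
    baseline_solution: dict     # warm-start calibration at cohort baselines


@dataclass(frozen=True)
class SyntheticSubjectBundle:
    """One subject's record, raw derivatives and ground-truth targets."""

    record: SubjectRecord
    counts: StreamlineCountMatrix
    fa: FAEdgeMatrix
    timeseries: RoiTimeSeries
    targets: dict               # (modality, compartment) -> planted value
    factors: dict               # modality -> latent coherence factor


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimulationConfig
    seed: int
    atlas: AtlasDefinition
    template: EdgeTemplate
    bundles: tuple

    @property
    def records(self):
        return [b.record for b in self.bundles]


def cohort_atlas(config: SimulationConfig) -> AtlasDefinition:
    """Atlas matching the configured region count (packaged atlas at 246)."""
    if config.n_regions == 246:
        return default_atlas()
    return make_atlas(config.n_regions)


# ---------------------------------------------------------------------------
# edge template and EW calibration


def build_template(config: SimulationConfig,
                   rng: np.random.Generator) -> EdgeTemplate:
    """Draw the cohort edge topology and solve the baseline calibration."""
    r = config.n_regions
    left = np.arange(0, r, 2)    # region ids 1,3,5,... (odd -> left)
    right = np.arange(1, r, 2)
    pools = {
        "intra_left": np.array([(i, j) for k, i in enumerate(left)
                                for j in left[k + 1:]]),
        "intra_right": np.array([(i, j) for k, i in enumerate(right)
                                 for j in right[k + 1:]]),
        "inter": np.array([(i, j) if i < j else (j, i)
                           for i in left for j in right]),
    }
    comp_code = {"intra_left": CODE_INTRA_LEFT,
                 "intra_right": CODE_INTRA_RIGHT, "inter": CODE_INTER}
    ii, jj, rates, comps = [], [], [], []
    for key, pool in pools.items():
        pick = rng.choice(len(pool), size=config.n_edges[key], replace=False)
        chosen = pool[np.sort(pick)]
        lo, hi = (config.rate_range_inter if key == "inter"
                  else config.rate_range_intra)
        ii.append(chosen[:, 0])
        jj.append(chosen[:, 1])
        rates.append(rng.uniform(lo, hi, size=len(chosen)))
        comps.append(np.full(len(chosen), comp_code[key], dtype=np.int8))
    edge_i = np.concatenate(ii)
    edge_j = np.concatenate(jj)
    edge_rate = np.concatenate(rates)
    edge_comp = np.concatenate(comps)
    baseline = {comp: config.baseline_means[("EW", comp)]
                for comp in COMPARTMENTS}
    template = EdgeTemplate(r, edge_i, edge_j, edge_rate, edge_comp, {})
    solution = calibrate_ew_scales(template, baseline)
    return replace(template, baseline_solution=solution)


_COMP_ORDER = ("left", "right", "inter")


def _comp_index(template: EdgeTemplate) -> np.ndarray:
    codes = [_CODE_BY_COMPARTMENT[c] for c in _COMP_ORDER]
    idx = np.empty(len(template.edge_comp), dtype=np.intp)
    for k, code in enumerate(codes):
        idx[template.edge_comp == code] = k
    return idx


def _expected_compartment_ew(template: EdgeTemplate, scales: dict,
                             background: float,
                             comp_idx: np.ndarray | None = None):
    """Expected compartment EW means under block scales and background."""
    if comp_idx is None:
        comp_idx = _comp_index(template)
    scale_vec = np.array([scales[c] for c in _COMP_ORDER])
    rate = template.edge_rate * scale_vec[comp_idx]
    # background is spread uniformly over non-template pairs only, so a
    # region with template degree d receives b * (1 - d / (R - 1)) of it
    ones = np.ones(len(rate))
    degree = (np.bincount(template.edge_i, weights=ones,
                          minlength=template.n_regions)
              + np.bincount(template.edge_j, weights=ones,
                            minlength=template.n_regions))
    strengths = (np.bincount(template.edge_i, weights=rate,
                             minlength=template.n_regions)
                 + np.bincount(template.edge_j, weights=rate,
                               minlength=template.n_regions)
                 + background * (1.0 - degree / (template.n_regions - 1)))
    denom = (strengths[template.edge_i] + strengths[template.edge_j]) / 2.0
    ew = rate / denom
    sums = np.bincount(comp_idx, weights=ew, minlength=3)
    counts = np.bincount(comp_idx, minlength=3)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return dict(zip(_COMP_ORDER, means))


def calibrate_ew_scales(template: EdgeTemplate, targets: dict,
                        warm_start: dict | None = None,
                        max_iter: int = 80, tol: float = 1e-4) -> dict:
    """Solve block scales + background so expected EW means hit the targets.

    The left scale is the gauge (fixed at the warm start value); the right
    and interhemispheric scales control the compartment ratios and the
    diffuse background strength controls the overall level.  Damped
    multiplicative fixed-point iteration; raises if the targets are
    infeasible for the template.
    """
    active = [c for c in COMPARTMENTS if targets[c] > 0]
    for comp in COMPARTMENTS:
        if targets[comp] < 0:
            raise SimulationError(
                f"EW target for compartment {comp!r} is negative")
    if "left" not in active or "right" not in active:
        raise SimulationError("intrahemispheric EW targets must be positive")
    if warm_start:
        scales = {c: warm_start[c] for c in COMPARTMENTS}
        background = warm_start["background"]
    else:
        scales = {c: 1.0 for c in COMPARTMENTS}
        background = 30.0
    if "inter" not in active:
        scales["inter"] = 0.0
    comp_idx = _comp_index(template)
    first = _expected_compartment_ew(template, scales, background, comp_idx)
    if any(np.isnan(first[c]) for c in active):
        raise SimulationError("a compartment with a positive EW target has "
                              "no template edges")
    damp = 0.7
    for _ in range(max_iter):
        means = _expected_compartment_ew(template, scales, background,
                                         comp_idx)
        ratios = {c: targets[c] / means[c] for c in active}
        ratios.setdefault("inter", 1.0)
        if max(abs(v - 1.0) for v in ratios.values()) < tol:
            break
        scales["right"] *= (ratios["right"] / ratios["left"]) ** damp
        scales["inter"] *= (ratios["inter"] / ratios["left"]) ** damp
        # the level responds to the background with elasticity ~ b / (S + b);
        # amplify the update accordingly so the level converges as fast as
        # the ratios
        mean_strength = (template.edge_rate
                         * np.array([scales[c] for c in _COMP_ORDER])[comp_idx]
                         ).sum() * 2.0 / template.n_regions + background
        elasticity = max(background / mean_strength, 0.05)
        background = max(
            background / ratios["left"] ** min(damp / elasticity, 8.0), 1e-9)
    means = _expected_compartment_ew(template, scales, background, comp_idx)
    err = max(abs(means[c] / targets[c] - 1.0) for c in active)
    if err > 0.02:
        raise SimulationError(
            f"EW targets {targets} infeasible for this edge template "
            f"(closest achievable {means})")
    return {**scales, "background": background}


# ---------------------------------------------------------------------------
# per-subject realizations


def sample_counts(ew_targets: dict, template: EdgeTemplate,
                  rng: np.random.Generator,
                  subject_id: str = "") -> StreamlineCountMatrix:
    """Poisson streamline counts whose expected compartment EW means match
    the subject's targets (template edges plus diffuse background)."""
    solution = calibrate_ew_scales(template, ew_targets,
                                   warm_start=template.baseline_solution
                                   or None)
    r = template.n_regions
    per_edge_scale = np.empty_like(template.edge_rate)
    for comp, code in _CODE_BY_COMPARTMENT.items():
        per_edge_scale[template.edge_comp == code] = solution[comp]
    bg_rate = solution["background"] / (r - 1)
    rate = np.full((r, r), bg_rate)
    rate[template.edge_i, template.edge_j] = (template.edge_rate
                                              * per_edge_scale)
    iu, ju = np.triu_indices(r, k=1)
    draws = rng.poisson(rate[iu, ju])
    counts = np.zeros((r, r), dtype=np.int64)
    counts[iu, ju] = draws
    counts += counts.T
    return StreamlineCountMatrix(counts, subject_id)


def sample_fa_edges(counts: StreamlineCountMatrix, fa_targets: dict,
                    noise_sd: float, codes: np.ndarray,
                    rng: np.random.Generator,
                    subject_id: str = "") -> FAEdgeMatrix:
    """Per-edge FA around the compartment target wherever streamlines exist."""
    r = counts.n_regions
    target = np.zeros((r, r))
    for comp, code in _CODE_BY_COMPARTMENT.items():
        value = fa_targets[comp]
        if not 0.0 < value < 1.0:
            raise SimulationError(
                f"FA target {value} for compartment {comp!r} outside (0, 1)")
        target[codes == code] = value
    fa = np.full((r, r), np.nan)
    iu, ju = np.triu_indices(r, k=1)
    support = counts.counts[iu, ju] > 0
    noisy = (target[iu, ju][support]
             + noise_sd * rng.standard_normal(int(support.sum())))
    fa[iu[support], ju[support]] = np.clip(noisy, 1e-3, 1.0 - 1e-3)
    fa[ju[support], iu[support]] = fa[iu[support], ju[support]]
    return FAEdgeMatrix(fa, subject_id)


def sample_timeseries(fc_targets: dict, n_timepoints: int, is_left: np.ndarray,
                      rng: np.random.Generator,
                      subject_id: str = "") -> RoiTimeSeries:
    """Gaussian factor-model time series with block correlation structure.

    Within-hemisphere correlations equal tanh of the left/right Fisher-z
    targets, between-hemisphere correlations equal tanh of the
    interhemispheric target.  Infeasible (non-positive-definite) block
    requests are repaired to the nearest feasible structure with a warning.
    """
    a_left = np.tanh(fc_targets["left"])
    a_right = np.tanh(fc_targets["right"])
    c_inter = np.tanh(fc_targets["inter"])
    if a_left < 0 or a_right < 0:
        raise SimulationError("negative within-hemisphere FC targets are not "
                              "representable by the block factor model")
    if a_left > 0 and a_right > 0:
        rho = c_inter / np.sqrt(a_left * a_right)
        if abs(rho) > 1.0:
            logger.warning("subject %s: interhemispheric FC target %.3f "
                           "exceeds the feasible block structure; repaired "
                           "to the nearest feasible value", subject_id,
                           fc_targets["inter"])
            rho = np.clip(rho, -0.999, 0.999)
    else:
        if c_inter != 0:
            logger.warning("subject %s: interhemispheric FC target dropped "
                           "(a within-hemisphere target is zero)", subject_id)
        rho = 0.0
    n_regions = len(is_left)
    f = rng.standard_normal((n_timepoints, 2))
    f_left = f[:, 0]
    f_right = rho * f[:, 0] + np.sqrt(1.0 - rho ** 2) * f[:, 1]
    noise = rng.standard_normal((n_timepoints, n_regions))
    x = np.empty((n_timepoints, n_regions))
    x[:, is_left] = (np.sqrt(a_left) * f_left[:, None]
                     + np.sqrt(1.0 - a_left) * noise[:, is_left])
    x[:, ~is_left] = (np.sqrt(a_right) * f_right[:, None]
                      + np.sqrt(1.0 - a_right) * noise[:, ~is_left])
    return RoiTimeSeries(x, subject_id)


# ---------------------------------------------------------------------------
# demographics, targets and cohort assembly


def _sample_truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if lo <= value < hi:
            return float(value)
    raise SimulationError(f"could not draw a value in [{lo}, {hi}) around "
                          f"{mean} +/- {sd}")


def _sample_records(config: SimulationConfig,
                    rng: np.random.Generator):
    records = []
    for group in GROUPS:
        mean, sd = config.age_params[group]
        lo, hi = config.age_bounds
        for k in range(config.group_sizes[group]):
            subject_id = f"{group}_{k + 1:02d}"
            age = _sample_truncated_normal(rng, mean, sd, lo, hi)
            sex = "m" if rng.random() < config.male_prob[group] else "f"
            if group == "control":
                lesion = "none"
            else:
                lesion = ("left" if rng.random()
                          < config.lesion_left_prob[group] else "right")
            records.append(SubjectRecord(subject_id, group, lesion,
                                         age, sex))
    return records


def draw_subject_targets(config: SimulationConfig, record: SubjectRecord,
                         rng: np.random.Generator):
    """Sample the subject's 3 x 3 compartment-target grid and its factors."""
    factors = {mod: float(rng.standard_normal()) for mod in MODALITIES}
    lam = config.loadings[record.group]
    targets = {}
    for mod in MODALITIES:
        for comp in COMPARTMENTS:
            mu = config.baseline_means[(mod, comp)]
            scale = config.subject_scale[(mod, comp)]
            delta = 0.0
            if mod == "EW" and comp == "inter" and record.group != "control":
                delta = config.delta_ew_inter_patients
            if mod == "FA" and record.group == "IDHwt" \
                    and comp == record.lesion_hemisphere:
                delta = config.delta_fa_ipsi_idhwt
            if mod == "FA" and record.group == "IDHmut" \
                    and comp in ("left", "right") \
                    and comp != record.lesion_hemisphere:
                delta = config.delta_fa_contra_idhmut
            value = mu + delta + scale * (lam[mod] * factors[mod]
                                          + config.resid_sd
                                          * rng.standard_normal())
            if mod in ("EW", "FA") and not 0.0 < value < 1.0:
                raise SimulationError(
                    f"subject {record.subject_id}: infeasible {mod} target "
                    f"{value:.4f} in compartment {comp!r}")
            targets[(mod, comp)] = float(value)
    return targets, factors


def simulate_cohort(config: SimulationConfig, seed: int) -> SimulatedCohort:
    """Generate a full synthetic cohort, deterministic in (config, seed)."""
    atlas = cohort_atlas(config)
    codes = compartment_codes(atlas)
    is_left = atlas.is_left
    n_subjects = sum(config.group_sizes[g] for g in GROUPS)
    streams = np.random.SeedSequence(seed).spawn(n_subjects + 2)
    template = build_template(config, np.random.default_rng(streams[0]))
    records = _sample_records(config, np.random.default_rng(streams[1]))
    bundles = []
    for record, stream in zip(records, streams[2:]):
        rng = np.random.default_rng(stream)
        targets, factors = draw_subject_targets(config, record, rng)
        ew_t = {c: targets[("EW", c)] for c in COMPARTMENTS}
        fa_t = {c: targets[("FA", c)] for c in COMPARTMENTS}
        fc_t = {c: targets[("FC", c)] for c in COMPARTMENTS}
        counts = sample_counts(ew_t, template, rng, record.subject_id)
        fa = sample_fa_edges(counts, fa_t, config.fa_noise_sd, codes, rng,
                             record.subject_id)
        ts = sample_timeseries(fc_t, config.n_timepoints, is_left, rng,
                               record.subject_id)
        bundles.append(SyntheticSubjectBundle(record, counts, fa, ts,
                                              targets, factors))
    return SimulatedCohort(config=copy.deepcopy(config), seed=seed,
                           atlas=atlas, template=template,
                           bundles=tuple(bundles))
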