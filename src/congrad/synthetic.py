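"""Synthetic multi-subject data with known ground truth.

The generator emulates the three inputs of the connectopic pipeline:

* BOLD-like runs whose ROI voxels load onto a small number of smooth,
  mutually orthogonal spatial modes, each connected to distinct
  out-of-ROI network parcels (mixing weights are a softmax over affine
  functions of the planted mode values, so connectivity changes smoothly
  and monotonically along each mode);
* "receptor" template maps that are low-order polynomial surfaces over the
  ROI whose generating coefficients have a requested correlation with a
  planted mode's trend-surface coefficients;
* a behavioral table whose symptom scores carry a planted monotone link to
  a per-subject similarity value.

The ROI is two fused ellipsoids (an elongated body plus an anterior bulb),
echoing the hippocampus-amygdala long-axis geometry that makes the
dominant gradient interpretable. Everything is deterministic given the
scenario seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm

from .errors import ArgumentError, ConfigurationError
from .image_io import BoldRun, MaskedVolume, world_coordinates
from .trend_surface import design_matrix, fit_tsm

#: softmax inverse temperature of the mode -> network mixing weights;
#: large enough that mode extremes couple almost exclusively (>0.99
#: correlation) to their network, small enough that loadings stay close
#: to linear in the mode value across the ROI.
MIXING_BETA = 1.5

#: geometric decay of the mixing gain for higher modes, giving the planted
#: modes a hierarchical share of connectivity variance.
MODE_GAIN_DECAY = 0.85

_PARCEL_ANCHORS = [
    (2, 2, 2), (18, 2, 2), (2, 2, 18), (18, 2, 18),
    (2, 18, 2), (18, 18, 2), (2, 18, 18), (18, 18, 18),
]


@dataclasses.dataclass
class SyntheticScenario:
    """Fixed description of one synthetic cohort."""

    grid_shape: tuple = (24, 24, 24)
    roi_spec: dict | None = None
    n_modes: int = 2
    n_networks: int = 4
    n_timepoints: int = 200
    n_subjects: int = 20
    noise_sd: float = 0.5
    subject_jitter_sd: float = 0.05
    behavior_effect: float = 0.3
    seed: int = 7

    # derived, filled by make_scenario
    affine: np.ndarray | None = None
    roi_mask: np.ndarray | None = None
    gm_mask: np.ndarray | None = None
    parcel_labels: np.ndarray | None = None


@dataclasses.dataclass
class GroundTruth:
    """Planted quantities the pipeline is expected to recover."""

    mode_maps: list            # MaskedVolume per planted mode
    mode_matrix: np.ndarray    # ROI voxel x n_modes, scaled to max |.| = 1
    template_tsm: np.ndarray | None = None   # generating coefficient vectors
    behavior_link: np.ndarray | None = None  # per-subject latent similarity


def _ellipsoid_mask(shape, center, semiaxes):
    idx = np.indices(shape, dtype=float)
    d = sum(((idx[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return d <= 1.0


def _default_roi_spec():
    # elongated body along Y plus an anterior bulb, ~300 voxels on 24^3
    return {
        "body_center": (12.0, 10.0, 12.0),
        "body_semiaxes": (3.1, 7.0, 3.1),
        # bulb placed so the ROI's y-extent is symmetric about an integer
        # plane: the long-axis mode then takes its exact midpoint value on
        # a voxel plane instead of straddling it
        "bulb_center": (12.0, 17.0, 12.0),
        "bulb_radius": 2.8,
    }


def make_scenario(**config) -> SyntheticScenario:
    """Build and validate a scenario; deterministic given the seed."""
    sc = SyntheticScenario(**config)
    if sc.n_modes < 1:
        raise ConfigurationError("n_modes must be >= 1")
    if sc.n_networks < sc.n_modes + 1:
        raise ConfigurationError(
            f"n_networks ({sc.n_networks}) must be >= n_modes + 1 "
            f"({sc.n_modes + 1})")
    if sc.n_networks > len(_PARCEL_ANCHORS):
        raise ConfigurationError(
            f"at most {len(_PARCEL_ANCHORS)} network parcels supported")
    if sc.n_timepoints < 2 or sc.n_subjects < 1:
        raise ConfigurationError("need >= 2 timepoints and >= 1 subject")
    if sc.noise_sd < 0 or sc.subject_jitter_sd < 0:
        raise ConfigurationError("noise/jitter SDs must be non-negative")
    if not -1.0 <= sc.behavior_effect <= 1.0:
        raise ConfigurationError("behavior_effect must lie in [-1, 1]")
    spec = sc.roi_spec or _default_roi_spec()
    sc.roi_spec = spec
    shape = tuple(int(s) for s in sc.grid_shape)
    sc.grid_shape = shape
    roi = _ellipsoid_mask(shape, spec["body_center"], spec["body_semiaxes"])
    roi |= _ellipsoid_mask(shape, spec["bulb_center"],
                           (spec["bulb_radius"],) * 3)
    if int(roi.sum()) < 50:
        raise ConfigurationError(
            f"ROI has {int(roi.sum())} voxels; need >= 50")
    # 2 mm isotropic grid centered on the world origin
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1)
    labels = np.zeros(shape, dtype=int)
    scale = np.asarray(shape) / 24.0
    for j in range(sc.n_networks):
        a = np.round(np.asarray(_PARCEL_ANCHORS[j]) * scale).astype(int)
        block = tuple(slice(int(a[i]), int(a[i]) + 3) for i in range(3))
        labels[block] = j + 1
    labels[roi] = 0
    gm = labels > 0
    if any(np.bincount(labels.ravel())[1:sc.n_networks + 1] == 0):
        raise ConfigurationError("a network parcel fell outside the grid")
    sc.affine = aff
    sc.roi_mask = roi
    sc.gm_mask = gm
    sc.parcel_labels = labels
    return sc


def planted_modes(scenario: SyntheticScenario) -> GroundTruth:
    """Planted gradient modes: smooth polynomial fields over the ROI,
    demeaned, Gram-Schmidt orthogonalized, scaled to max |value| = 1."""
    ref = MaskedVolume(np.zeros(int(scenario.roi_mask.sum())),
                       scenario.roi_mask, scenario.affine, name="roi")
    xyz = world_coordinates(ref)
    x, y, z = (xyz[:, i] for i in range(3))
    # long-axis first, then progressively finer structure
    candidates = [y, y ** 2, x, z, y ** 3, x * 0 + y * x, z * y, x ** 2]
    if scenario.n_modes > len(candidates):
        raise ConfigurationError(
            f"at most {len(candidates)} planted modes supported")
    basis = []
    for j in range(scenario.n_modes):
        v = candidates[j] - candidates[j].mean()
        for u in basis:
            v = v - (v @ u) / (u @ u) * u
        if np.max(np.abs(v)) < 1e-9:
            raise ConfigurationError("degenerate planted mode geometry")
        basis.append(v)
    # affine map each mode onto [-1, 1]; demeaned orthogonality survives
    # the rescaling and the softmax-neutral point sits at the range midpoint
    modes = np.column_stack([
        2.0 * (v - v.min()) / (v.max() - v.min()) - 1.0 for v in basis])
    maps = [MaskedVolume(modes[:, j], scenario.roi_mask, scenario.affine,
                         name=f"planted-mode-{j}")
            for j in range(scenario.n_modes)]
    return GroundTruth(mode_maps=maps, mode_matrix=modes)


def _subject_mode_matrix(scenario, truth, subject_index):
    """Per-subject jitter: small random rotation in mode space."""
    if scenario.n_modes == 1 or scenario.subject_jitter_sd == 0:
        return truth.mode_matrix
    rng = np.random.default_rng([scenario.seed, 7919, subject_index])
    k = scenario.n_modes
    skew = rng.normal(0.0, scenario.subject_jitter_sd, size=(k, k))
    skew = (skew - skew.T) / 2.0
    return truth.mode_matrix @ expm(skew)


def _mixing_weights(mode_matrix, n_networks):
    """Softmax over affine functions of mode values -> voxel x network."""
    n_vox, n_modes = mode_matrix.shape
    u = np.zeros((n_vox, n_networks))
    for j in range(n_networks):
        mode = (j // 2) % n_modes
        sign = 1.0 if j % 2 == 0 else -1.0
        gain = MIXING_BETA * MODE_GAIN_DECAY ** mode
        if j < 2 * n_modes:
            u[:, j] = sign * gain * mode_matrix[:, mode]
        # parcels beyond 2*n_modes stay at baseline (u = 0)
    e = np.exp(u - u.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def generate_bold(scenario: SyntheticScenario, subject_index: int,
                  truth: GroundTruth | None = None) -> BoldRun:
    """One subject's BOLD run with planted connectivity gradients.

    ROI voxel v: ``sum_k w_k(v) s_k(t) + noise``; each out-of-ROI parcel
    carries its own unit-variance network signal ``s_k`` plus noise.
    Deterministic for a given (scenario seed, subject index).
    """
    if not 0 <= subject_index < scenario.n_subjects:
        raise ArgumentError(f"subject_index {subject_index} out of range")
    if truth is None:
        truth = planted_modes(scenario)
    rng = np.random.default_rng([scenario.seed, 104729, subject_index])
    t, nn = scenario.n_timepoints, scenario.n_networks
    signals = rng.standard_normal((t, nn))
    signals = (signals - signals.mean(axis=0)) / signals.std(axis=0)
    modes = _subject_mode_matrix(scenario, truth, subject_index)
    w = _mixing_weights(modes, nn)
    roi_ts = signals @ w.T
    roi_ts += scenario.noise_sd * rng.standard_normal(roi_ts.shape)
    labels = scenario.parcel_labels
    inbrain = scenario.roi_mask | scenario.gm_mask
    n_in = int(inbrain.sum())
    data = np.empty((t, n_in))
    roi_in = scenario.roi_mask[inbrain]
    data[:, roi_in] = roi_ts
    lab_in = labels[inbrain]
    for j in range(nn):
        cols = lab_in == j + 1
        n_cols = int(cols.sum())
        series = signals[:, [j]] + scenario.noise_sd * \
            rng.standard_normal((t, n_cols))
        data[:, cols] = series
    return BoldRun(data, scenario.roi_mask, scenario.gm_mask,
                   scenario.affine, tr_seconds=2.0,
                   subject_id=f"sub-{subject_index:03d}")


def generate_templates(scenario: SyntheticScenario,
                       correlation_targets: dict | None = None,
                       n_templates: int = 18, order_k: int = 9,
                       truth: GroundTruth | None = None):
    """Polynomial "receptor" templates over the ROI.

    ``correlation_targets`` maps template index -> (mode index, target r);
    those templates get a generating coefficient vector whose Pearson
    correlation with the planted mode's fitted TSM coefficients equals the
    target exactly (so the fitted-coefficient correlation lands within a
    hair of it). Remaining templates get random coefficients. Returns
    ``(templates, truth)`` with the generating vectors recorded in
    ``truth.template_tsm``.
    """
    if truth is None:
        truth = planted_modes(scenario)
    correlation_targets = dict(correlation_targets or {})
    for idx, (mode, rho) in correlation_targets.items():
        if not -1.0 <= rho <= 1.0:
            raise ArgumentError(f"correlation target {rho} outside [-1, 1]")
        if not 0 <= mode < scenario.n_modes:
            raise ArgumentError(f"no planted mode {mode}")
        if not 0 <= idx < n_templates:
            raise ArgumentError(f"template index {idx} out of range")
    rng = np.random.default_rng([scenario.seed, 15485863])
    mode_slopes = [fit_tsm(m, order_k).slopes for m in truth.mode_maps]
    ref = truth.mode_maps[0]
    xdes, _ = design_matrix(world_coordinates(ref), order_k)
    coeffs = np.empty((n_templates, order_k))
    for i in range(n_templates):
        if i in correlation_targets:
            mode, rho = correlation_targets[i]
            c0 = mode_slopes[mode] - mode_slopes[mode].mean()
            chat = c0 / np.linalg.norm(c0)
            zraw = rng.standard_normal(order_k)
            z0 = zraw - zraw.mean()
            z0 -= (z0 @ chat) * chat
            nz = np.linalg.norm(z0)
            if nz < 1e-12:  # essentially impossible; redraw deterministic
                z0 = np.roll(chat, 1) - np.roll(chat, 1).mean()
                z0 -= (z0 @ chat) * chat
                nz = np.linalg.norm(z0)
            coeffs[i] = rho * chat + np.sqrt(max(0.0, 1 - rho ** 2)) * z0 / nz
        else:
            coeffs[i] = rng.standard_normal(order_k)
    templates = [
        MaskedVolume(xdes @ coeffs[i], scenario.roi_mask, scenario.affine,
                     name=f"template-{i:02d}")
        for i in range(n_templates)
    ]
    truth.template_tsm = coeffs
    return templates, truth


# plausible questionnaire ranges: (low, high, center, spread)
_SCORE_RANGES = {"ids_sr": (0, 84, 42.0, 14.0), "asi": (0, 64, 32.0, 10.0)}


def _linked_score(rng, sim, effect, lo, hi, center, spread):
    n = len(sim)
    ranks = stats.rankdata(sim)
    zeta = (ranks - 0.5) / n - 0.5
    zeta *= np.sqrt(12.0)  # approx unit variance
    latent = effect * zeta + np.sqrt(max(0.0, 1 - effect ** 2)) * \
        rng.standard_normal(n)
    return np.clip(np.round(center + spread * latent), lo, hi).astype(int)


def generate_behavior(scenario: SyntheticScenario,
                      per_subject_similarity) -> pd.DataFrame:
    """Behavioral/covariate table with a planted monotone brain link.

    Depressive (IDS-SR, 0-84) and anxiety (ASI, 0-64) sum scores follow
    ``behavior_effect * rank(similarity) + noise`` mapped onto integer
    questionnaire ranges; trauma and comorbidity are independent of the
    similarity, as are the covariates.
    """
    sim = np.asarray(per_subject_similarity, dtype=float)
    n = sim.size
    if n != scenario.n_subjects:
        raise ArgumentError(
            f"{n} similarity values for {scenario.n_subjects} subjects")
    rng = np.random.default_rng([scenario.seed, 32452843])
    e = scenario.behavior_effect
    ids = _linked_score(rng, sim, e, *_SCORE_RANGES["ids_sr"])
    asi = _linked_score(rng, sim, e, *_SCORE_RANGES["asi"])
    subs = np.clip(np.round(rng.lognormal(2.0, 0.35, size=(n, 3))),
                   5, 25).astype(int)
    comorbidity = rng.binomial(5, 0.35, size=n)
    age = rng.integers(18, 66, size=n)
    sex = rng.integers(0, 2, size=n)
    motion = rng.lognormal(np.log(0.123), 0.35, size=n)
    medication = (rng.random(n) < 0.3).astype(int)
    return pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "ids_sr": ids, "asi": asi,
        "trauma_total": subs.sum(axis=1),
        "trauma_sub1": subs[:, 0], "trauma_sub2": subs[:, 1],
        "trauma_sub3": subs[:, 2],
        "comorbidity": comorbidity,
        "age": age, "sex": sex, "motion": motion, "medication": medication,
    })


def planted_similarity(scenario: SyntheticScenario,
                       truth: GroundTruth | None = None,
                       template_index: int = 0, mode_index: int = 0,
                       order_k: int = 9) -> np.ndarray:
    """Ground-truth per-subject similarity: atanh(|r|) between each
    subject's jittered mode TSM slopes and a template's generating
    coefficients. Used as the latent behind ``generate_behavior``."""
    if truth is None or truth.template_tsm is None:
        _, truth = generate_templates(scenario, truth=truth)
    tvec = truth.template_tsm[template_index]
    out = np.empty(scenario.n_subjects)
    for s in range(scenario.n_subjects):
        modes = _subject_mode_matrix(scenario, truth, s)
        vol = MaskedVolume(modes[:, mode_index], scenario.roi_mask,
                           scenario.affine, name=f"sub-{s:03d}-mode")
        slopes = fit_tsm(vol, order_k).slopes
        r = np.corrcoef(slopes, tvec)[0, 1]
        out[s] = np.arctanh(min(abs(float(r)), 1 - 1e-12))
    truth.behavior_link = out
    return out
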