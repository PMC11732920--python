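"""Synthetic multi-subject ROI BOLD cohorts with known network truth.

Emulates the design of a two-group (patients vs. controls) resting-state
study: ~200 volumes at TR = 2.5 s, a shared ground-truth connectivity
backbone, a set of *affected* ROIs whose edges are attenuated in patients,
group-specific head motion (patients move more), WM/CSF and motion confound
leakage into the ROI signals, and a cognitive score linearly coupled to
each subject's *true* nodal efficiency at the affected ROIs — so every
downstream stage (denoising, thresholding, graph metrics, group GLM,
brain–behavior correlation) has a recoverable ground truth.

The generator produces ROI-level tables only; no volumetric images and no
hemodynamic modeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph

from .connectivity import ConnectivityMatrix
from .parcellation import ParcellationSpec, anatomical26

GROUPS = ("patient", "control")


@dataclass(frozen=True)
class CohortConfig:
    """All tunables of the synthetic study.

    Defaults mirror the emulated study: 17 patients vs. 20 controls with
    usable data, 200 volumes at TR 2.5 s, one affected vermal ROI in the
    26-ROI anatomical scheme, and motion amplitudes that reproduce group
    mean relative RMS of ~0.05 (patients) vs ~0.02 mm (controls).
    """

    n_patients: int = 17
    n_controls: int = 20
    n_volumes: int = 200
    tr_seconds: float = 2.5
    parcellation: ParcellationSpec = field(default_factory=anatomical26)
    affected_rois: tuple = ("Vermis_8",)
    edge_attenuation: float = 0.4        # fraction removed from affected edges in patients
    attenuation_subject_sd: float = 0.08  # per-subject jitter of the attenuation
    base_correlation: float = 0.45       # mean off-diagonal ground-truth correlation
    correlation_spread: float = 0.15     # heterogeneity of backbone weights
    subject_spread: float = 0.05         # per-subject jitter of the backbone weights
    ar1_coefficient: float = 0.3         # temporal autocorrelation of the BOLD-like signal
    confound_loadings: dict = field(
        default_factory=lambda: {"motion": 0.3, "wm": 0.3, "csf": 0.3})
    motion_amplitude_by_group: dict = field(
        default_factory=lambda: {"patient": 0.054, "control": 0.022})  # mm (deg) per step
    motion_amplitude_cv: float = 0.45    # across-subject spread of the step amplitude
    behavior_coupling: float = 58.0      # score points per unit true efficiency
    behavior_intercept: float = 40.0     # score points
    behavior_noise_sd: float = 3.0       # score points
    noise_sd: float = 0.3                # observation noise, signal units
    backbone_seed: int = 42              # fixes the population truth network
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_volumes < 3:
            raise ValueError("need at least 3 volumes")
        if not 0.0 <= self.edge_attenuation < 1.0:
            raise ValueError("edge_attenuation must lie in [0, 1)")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        for label in self.affected_rois:
            self.parcellation.index_of(label)  # raises KeyError if unknown
        object.__setattr__(self, "affected_rois", tuple(self.affected_rois))


@dataclass
class SubjectRecord:
    """One simulated participant."""

    subject_id: str
    group: str
    age: float
    sex: str                      # "F" or "M"
    timeseries: np.ndarray        # (n_volumes, n_rois), BOLD-like units
    motion: np.ndarray            # (n_volumes, 6): 3 translations mm, 3 rotations deg
    nuisance: np.ndarray          # (n_volumes, 2): WM, CSF
    cognitive_scores: dict = field(default_factory=dict)
    true_affected_efficiency: float = float("nan")

    def __post_init__(self):
        n = self.timeseries.shape[0]
        if self.motion.shape != (n, 6):
            raise ValueError("motion trace must be (n_volumes, 6)")
        if self.nuisance.shape != (n, 2):
            raise ValueError("nuisance must be (n_volumes, 2)")
        if np.isnan(self.timeseries).any():
            raise ValueError("timeseries contains missing values")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass
class CohortTruth:
    """Ground truth returned alongside the simulated records."""

    ground_truth: dict            # group -> ConnectivityMatrix
    true_nodal_efficiency: dict   # group -> per-node efficiency of the truth graph
    affected_rois: tuple
    subject_true_efficiency: dict  # subject_id -> mean affected-node true efficiency


def _psd_repair(w: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at 0, then rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(w)
    if vals.min() >= 0:
        return w
    vals = np.clip(vals, 0.0, None)
    w = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(w))
    d[d == 0] = 1.0
    w = w / np.outer(d, d)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return w


def _backbone(config: CohortConfig) -> np.ndarray:
    """Control-group ground-truth correlation backbone (heterogeneous).

    Seeded by ``backbone_seed``, not ``seed``: the truth network is a fixed
    population object, and varying the cohort seed re-samples subjects from
    the same population (replicating the study) rather than changing the
    universe under study.
    """
    n = config.parcellation.n_rois
    rng = np.random.default_rng(np.random.SeedSequence([config.backbone_seed, 0xBACB]))
    w = np.full((n, n), config.base_correlation)
    if config.correlation_spread > 0:
        w = w + _symmetric_jitter(n, config.correlation_spread, rng)
    w = np.clip(w, -0.95, 0.95)
    np.fill_diagonal(w, 1.0)
    return _psd_repair(w)


def _symmetric_jitter(n: int, sd: float, rng) -> np.ndarray:
    """Symmetric zero-diagonal Gaussian perturbation with entry sd ``sd``."""
    jit = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    jit[iu] = rng.normal(0.0, sd, size=iu[0].size)
    return jit + jit.T


def _attenuate(w: np.ndarray, idx: np.ndarray, attenuation: float) -> np.ndarray:
    """Scale off-diagonal entries incident to ``idx`` by (1 - attenuation)."""
    if attenuation == 0 or idx.size == 0:
        return w.copy()
    mask = np.zeros(w.shape[0], dtype=bool)
    mask[idx] = True
    incident = mask[:, None] | mask[None, :]
    np.fill_diagonal(incident, False)
    out = w.copy()
    out[incident] *= 1.0 - attenuation
    np.fill_diagonal(out, 1.0)
    out = np.clip(out, -0.99, 0.99)
    np.fill_diagonal(out, 1.0)
    return _psd_repair(out)


def make_ground_truth(config: CohortConfig, group: str) -> ConnectivityMatrix:
    """Group-level ground-truth correlation matrix.

    Controls carry the backbone unchanged; in patients every off-diagonal
    entry incident to an affected ROI is multiplied by
    ``1 - edge_attenuation``. The result is PSD-repaired (eigenvalue
    clipping + unit-diagonal rescale) if the attenuation broke positive
    semi-definiteness.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    w = _backbone(config)
    if group == "patient":
        idx = np.array([config.parcellation.index_of(r) for r in config.affected_rois],
                       dtype=int)
        w = _attenuate(w, idx, config.edge_attenuation)
    return ConnectivityMatrix(labels=config.parcellation.roi_labels, weights=w)


def _true_efficiency(config: CohortConfig, w: np.ndarray) -> np.ndarray:
    """Weighted nodal global efficiency of a ground-truth correlation matrix.

    The truth is a weighted object, so true efficiency is read off the
    weighted graph (connection length 1/w over positive weights, shortest
    paths by Dijkstra, efficiency = mean inverse distance); binarization at
    a cost level is an analysis step, not part of the truth. The weighted
    definition varies continuously with the subject-level jitter, which is
    what makes behavior coupling to true efficiency a recoverable target.
    """
    n = w.shape[0]
    pos = np.clip(w, 0.0, None)
    np.fill_diagonal(pos, 0.0)
    with np.errstate(divide="ignore"):
        lengths = np.where(pos > 0, 1.0 / pos, 0.0)
    dist = csgraph.dijkstra(csr_matrix(lengths), directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return inv.sum(axis=1) / (n - 1)


def _reflect(x: np.ndarray, bound: float) -> np.ndarray:
    """Fold a walk back into [-bound, bound] (billiard reflection)."""
    period = 4.0 * bound
    y = np.mod(x + bound, period)
    y = np.where(y > 2.0 * bound, period - y, y)
    return y - bound


def _motion_trace(n: int, step_sd: float, rng) -> np.ndarray:
    """Reflected Gaussian random walk, 6 columns, clipped to +/-3 mm/deg."""
    steps = rng.normal(0.0, step_sd, size=(n, 6))
    steps[0] = 0.0
    return _reflect(np.cumsum(steps, axis=0), 3.0)


def _ar1_series(cov_chol: np.ndarray, n: int, phi: float, rng) -> np.ndarray:
    """Stationary AR(1) series whose cross-correlation matches the target.

    Spatially correlated innovations e_t = L z_t are filtered per ROI:
    x_t = phi x_{t-1} + sqrt(1 - phi^2) e_t, which leaves the stationary
    cross-correlation equal to L L^T while adding temporal smoothness.
    """
    n_rois = cov_chol.shape[0]
    e = rng.standard_normal((n, n_rois)) @ cov_chol.T
    if phi == 0:
        return e
    x = lfilter([np.sqrt(1.0 - phi ** 2)], [1.0, -phi], e, axis=0)
    # start near stationarity: overwrite the transient-prone first sample
    x[0] = e[0]
    return x


def _subject_attenuation(config: CohortConfig, group: str, rng) -> float:
    """Per-subject attenuation: group mean plus symmetric jitter.

    Negative values (possible for controls) mean stronger-than-average
    affected-node edges; keeping the jitter symmetric leaves the group
    means at exactly 0 and ``edge_attenuation``.
    """
    base = config.edge_attenuation if group == "patient" else 0.0
    a = base + rng.normal(0.0, config.attenuation_subject_sd)
    return float(np.clip(a, -0.5, 0.95))


def simulate_subject(config: CohortConfig, group: str, rng,
                     subject_id: str = "sub-00") -> SubjectRecord:
    """Simulate one participant from an externally supplied RNG state."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    n, n_rois = config.n_volumes, config.parcellation.n_rois
    idx = np.array([config.parcellation.index_of(r) for r in config.affected_rois],
                   dtype=int)

    att = _subject_attenuation(config, group, rng)
    w = _backbone(config)
    if config.subject_spread > 0:
        # individual connectomes deviate from the group backbone
        w = np.clip(w + _symmetric_jitter(n_rois, config.subject_spread, rng),
                    -0.95, 0.95)
        np.fill_diagonal(w, 1.0)
        w = _psd_repair(w)
    w = _attenuate(w, idx, att)
    chol = np.linalg.cholesky(w + 1e-10 * np.eye(n_rois))
    signal = _ar1_series(chol, n, config.ar1_coefficient, rng)

    group_amp = float(config.motion_amplitude_by_group[group])
    step_sd = float(np.clip(rng.normal(group_amp, config.motion_amplitude_cv * group_amp),
                            0.2 * group_amp, None))
    motion = _motion_trace(n, step_sd, rng)
    nuisance = _ar1_series(np.eye(2), n, 0.5, rng)

    # confound leakage: standardized confounds enter every ROI with a
    # loading-scaled, ROI-specific random weight
    loadings = np.concatenate([
        np.full(6, config.confound_loadings.get("motion", 0.0)),
        [config.confound_loadings.get("wm", 0.0)],
        [config.confound_loadings.get("csf", 0.0)],
    ])
    conf = np.column_stack([motion, nuisance])
    csd = conf.std(axis=0)
    csd[csd == 0] = 1.0
    conf_std = (conf - conf.mean(axis=0)) / csd
    mix = loadings[:, None] * rng.normal(1.0, 0.3, size=(8, n_rois))
    observed = signal + conf_std @ mix
    if config.noise_sd > 0:
        observed = observed + rng.normal(0.0, config.noise_sd, size=(n, n_rois))

    if idx.size:
        eff = float(_true_efficiency(config, w)[idx].mean())
    else:
        eff = float("nan")
    score = config.behavior_intercept + config.behavior_coupling * (eff if idx.size else 0.0)
    score += rng.normal(0.0, config.behavior_noise_sd)

    age = float(np.clip(rng.normal(29.0, 10.0), 18.0, 60.0))
    sex = "F" if rng.random() < 9.0 / 24.0 else "M"
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=age,
        sex=sex,
        timeseries=observed,
        motion=motion,
        nuisance=nuisance,
        cognitive_scores={"verbal_memory": float(score)},
        true_affected_efficiency=eff,
    )


def simulate_cohort(config: CohortConfig):
    """Simulate the full two-group cohort.

    Returns ``(records, truth)`` where ``truth`` is a :class:`CohortTruth`
    carrying the group ground-truth matrices, the true nodal efficiencies
    of their thresholded graphs, and each subject's true affected-node
    efficiency (the quantity the cognitive score is coupled to).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    records = []
    for i in range(config.n_patients):
        records.append(simulate_subject(config, "patient", rng, f"sub-P{i + 1:02d}"))
    for i in range(config.n_controls):
        records.append(simulate_subject(config, "control", rng, f"sub-C{i + 1:02d}"))

    ground_truth = {g: make_ground_truth(config, g) for g in GROUPS}
    true_eff = {g: _true_efficiency(config, ground_truth[g].weights) for g in GROUPS}
    truth = CohortTruth(
        ground_truth=ground_truth,
        true_nodal_efficiency=true_eff,
        affected_rois=config.affected_rois,
        subject_true_efficiency={r.subject_id: r.true_affected_efficiency
                                 for r in records},
    )
    return records, truth


# ---------------------------------------------------------------------------
# writers: plain-text TSV per subject + cohort table + JSON truth bundle

def write_cohort(records, truth: CohortTruth, out_dir, config: CohortConfig = None):
    """Serialize a cohort to a directory of TSV files and a JSON truth bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        roi_labels = (list(config.parcellation.roi_labels) if config is not None
                      else [f"roi{i}" for i in range(r.timeseries.shape[1])])
        pd.DataFrame(r.timeseries, columns=roi_labels).to_csv(
            out / f"{r.subject_id}_timeseries.tsv", sep="\t", index=False)
        pd.DataFrame(r.motion, columns=["tx_mm", "ty_mm", "tz_mm",
                                        "rx_deg", "ry_deg", "rz_deg"]).to_csv(
            out / f"{r.subject_id}_motion.tsv", sep="\t", index=False)
        pd.DataFrame(r.nuisance, columns=["wm", "csf"]).to_csv(
            out / f"{r.subject_id}_nuisance.tsv", sep="\t", index=False)
        row = {"subject_id": r.subject_id, "group": r.group,
               "age": r.age, "sex": r.sex}
        row.update(r.cognitive_scores)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    bundle = {
        "affected_rois": list(truth.affected_rois),
        "ground_truth": {g: truth.ground_truth[g].weights.tolist() for g in GROUPS},
        "roi_labels": list(truth.ground_truth["control"].labels),
        "true_nodal_efficiency": {g: truth.true_nodal_efficiency[g].tolist()
                                  for g in GROUPS},
        "subject_true_efficiency": truth.subject_true_efficiency,
    }
    (out / "truth.json").write_text(json.dumps(bundle, indent=1))


def read_cohort(in_dir):
    """Load a cohort previously written by :func:`write_cohort`.

    Returns ``(records, roi_labels)``; the truth bundle, if present, is not
    needed by the analysis pipeline and is left on disk.
    """
    src = Path(in_dir)
    table = pd.read_csv(src / "subjects.tsv", sep="\t")
    records = []
    roi_labels = None
    score_cols = [c for c in table.columns
                  if c not in ("subject_id", "group", "age", "sex")]
    for _, row in table.iterrows():
        sid = row["subject_id"]
        ts = pd.read_csv(src / f"{sid}_timeseries.tsv", sep="\t")
        roi_labels = list(ts.columns)
        motion = pd.read_csv(src / f"{sid}_motion.tsv", sep="\t").to_numpy(float)
        nuisance = pd.read_csv(src / f"{sid}_nuisance.tsv", sep="\t").to_numpy(float)
        records.append(SubjectRecord(
            subject_id=sid, group=row["group"], age=float(row["age"]),
            sex=row["sex"], timeseries=ts.to_numpy(float),
            motion=motion, nuisance=nuisance,
            cognitive_scores={c: float(row[c]) for c in score_cols},
        ))
    return records, roi_labels
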