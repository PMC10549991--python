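"""Mechano-regulation scoring: stimulus, phenotype classification, averaging,
stroke-peak selection and the amplitude parameter study.

The fate of mesenchymal stem cells on the scaffold surface is predicted
from the combined biophysical stimulus

    S = OSS / a + WSS / b,      a = 0.0375,  b = 10 mPa,

where OSS is the (dimensionless) octahedral shear strain of the solid and
WSS the wall shear stress of the medium at the same surface node.  The
banded thresholds map S to a phenotype:

    S <= 0.01        no differentiation (stimulus too low)
    0.01 < S <= 1    bone
    1 < S <= 3       cartilage
    3 < S <= 6       fibrous tissue
    S > 6            no differentiation (stimulus too high)

All interval boundaries are closed on the upper side.

Because the strain stimulus peaks at the piston's lowest position while the
flow stimulus peaks at maximum piston speed, the evaluation time is chosen
from the surface-averaged stimulus series S_avg(t) = OSS_avg/a + WSS_avg/b
(arithmetic nodal mean for OSS, area-weighted mean for WSS): its maxima on
the downward stroke (S_Max1) and upward stroke (S_Max2) are located and the
phenotype map is evaluated at the S_Max2 frame, the slightly higher of the
two.  ``run_parameter_study`` repeats this across compression amplitudes.

Viability diagnostics flag nodes outside empirically tolerated stimulus
ranges (OSS above 0.225 ~ strain-induced cell death; WSS above 57 mPa ~
apoptosis; WSS outside [0.01, 60] mPa ~ outside the differentiation
window); the flags never alter the S-based classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SurfaceMesh
from .loading import LoadProtocol, phase, piston_displacement, time_grid
from . import mechanics as _mech
from . import flow as _flow

__all__ = [
    "LABELS",
    "StimulusParams",
    "PhenotypeThresholds",
    "ViabilityLimits",
    "NodalFieldFrame",
    "PhenotypeMap",
    "PhenotypeDistribution",
    "Peak",
    "PeakPair",
    "stimulus",
    "classify",
    "oss_average",
    "wss_average",
    "s_avg_series",
    "detect_peaks",
    "phenotype_map_at",
    "distribution",
    "viability_flags",
    "generate_reduced_order_frames",
    "run_single_amplitude",
    "run_parameter_study",
    "AmplitudeResult",
    "StudyResult",
]

#: Phenotype labels in order of increasing stimulus band.
LABELS = ("none_low", "bone", "cartilage", "fibrous", "none_high")


@dataclass(frozen=True)
class StimulusParams:
    """Constants of the stimulus S = OSS/a + WSS/b (b in mPa)."""

    a: float = 0.0375
    b_mpa: float = 10.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b_mpa <= 0:
            raise ValueError("stimulus constants a and b must be > 0")


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Band edges of the phenotype classification (closed above)."""

    s_low: float = 0.01
    s_bone: float = 1.0
    s_cartilage: float = 3.0
    s_fibrous: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.s_low < self.s_bone < self.s_cartilage < self.s_fibrous:
            raise ValueError("thresholds must satisfy 0 < s_low < s_bone < s_cartilage < s_fibrous")

    def edges(self) -> np.ndarray:
        return np.array([self.s_low, self.s_bone, self.s_cartilage, self.s_fibrous])


@dataclass(frozen=True)
class ViabilityLimits:
    """Empirical viability bounds on the raw stimuli (WSS in mPa)."""

    oss_death: float = 0.225
    wss_apoptosis_mpa: float = 57.0
    wss_window_mpa: tuple[float, float] = (0.01, 60.0)


@dataclass
class NodalFieldFrame:
    """Co-located nodal OSS and WSS at one simulation time.

    ``oss`` dimensionless, ``wss_mpa`` in mPa, ``node_area`` in mm^2; all
    arrays share the surface-mesh node ordering.
    """

    time: float
    oss: np.ndarray
    wss_mpa: np.ndarray
    node_area: np.ndarray

    def __post_init__(self) -> None:
        self.oss = np.asarray(self.oss, dtype=float)
        self.wss_mpa = np.asarray(self.wss_mpa, dtype=float)
        self.node_area = np.asarray(self.node_area, dtype=float)
        n = self.oss.shape[0]
        if n == 0:
            raise ValueError("frame must contain at least one node")
        if self.wss_mpa.shape[0] != n or self.node_area.shape[0] != n:
            raise ValueError("oss, wss and node_area lengths must agree")
        if np.any(self.oss < 0) or np.any(self.wss_mpa < 0):
            raise ValueError("OSS and WSS must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.oss.shape[0]


@dataclass
class PhenotypeMap:
    """Per-node phenotype labels at one evaluation time."""

    labels: np.ndarray  # str array over LABELS
    time: float
    stimulus: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]


@dataclass
class PhenotypeDistribution:
    """Surface percentage per phenotype label (sums to 100)."""

    percentages: dict[str, float]
    amplitude_fraction: float | None = None
    time: float | None = None
    weighting: str = "node_count"

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.percentages[k] for k in LABELS}, name="percentage")


def stimulus(oss, wss_mpa, params: StimulusParams | None = None):
    """Combined stimulus S = OSS/a + WSS/b; vectorised over nodes."""
    params = params or StimulusParams()
    oss = np.asarray(oss, dtype=float)
    wss = np.asarray(wss_mpa, dtype=float)
    if np.any(oss < 0) or np.any(wss < 0):
        raise ValueError("OSS and WSS must be non-negative")
    s = oss / params.a + wss / params.b_mpa
    return s if s.ndim else float(s)


def classify(s, thresholds: PhenotypeThresholds | None = None):
    """Map stimulus value(s) to phenotype labels.

    Bands are closed above exactly as printed: S = s_low is still too low,
    S = s_bone is bone, S = s_cartilage is cartilage, S = s_fibrous is
    fibrous.
    """
    thresholds = thresholds or PhenotypeThresholds()
    s_arr = np.asarray(s, dtype=float)
    if np.any(~np.isfinite(s_arr)):
        raise ValueError("stimulus values must be finite")
    if np.any(s_arr < 0):
        raise ValueError("stimulus values must be >= 0")
    idx = np.searchsorted(thresholds.edges(), s_arr, side="left")
    out = np.asarray(LABELS, dtype="<U9")[idx]
    return out if out.ndim else str(out)


def oss_average(frame: NodalFieldFrame) -> float:
    """Arithmetic nodal mean of OSS over the scaffold surface."""
    return float(np.mean(frame.oss))


def wss_average(frame: NodalFieldFrame) -> float:
    """Area-weighted mean WSS over the scaffold surface, mPa."""
    total = frame.node_area.sum()
    if total <= 0:
        raise ValueError("total node area must be > 0")
    return float(np.sum(frame.wss_mpa * frame.node_area) / total)


def s_avg_series(
    frames: list[NodalFieldFrame], params: StimulusParams | None = None
) -> pd.DataFrame:
    """Surface-averaged stimulus time series.

    Per frame: average first, combine second — S_avg = OSS_avg/a +
    WSS_avg/b.  Returns columns ``t_s, oss_avg, wss_avg_mpa, s_avg``.
    """
    params = params or StimulusParams()
    if not frames:
        raise ValueError("at least one frame required")
    rows = []
    for fr in frames:
        o, w = oss_average(fr), wss_average(fr)
        rows.append((fr.time, o, w, stimulus(o, w, params)))
    return pd.DataFrame(rows, columns=["t_s", "oss_avg", "wss_avg_mpa", "s_avg"])


@dataclass(frozen=True)
class Peak:
    value: float
    time: float
    index: int


@dataclass(frozen=True)
class PeakPair:
    s_max1: Peak  # downward stroke
    s_max2: Peak  # upward stroke


def detect_peaks(series: pd.DataFrame, protocol: LoadProtocol) -> PeakPair:
    """Locate S_Max1 (downward stroke) and S_Max2 (upward stroke).

    The series must cover at least one full loading cycle.  Within each
    stroke the argmax is taken over the sampled frames; ties break toward
    the earlier time.  The half-period turning point belongs to the upward
    stroke, so S_Max2 is sought from the lowest piston position onward.
    """
    t = series["t_s"].to_numpy()
    s = series["s_avg"].to_numpy()
    if t.max() - t.min() < protocol.period - 1e-9:
        raise ValueError("series must cover at least one full loading cycle")
    ph = phase(t, protocol)
    peaks = {}
    for name, mask in (("downward", ph == "downward"), ("upward", ph == "upward")):
        if not np.any(mask):
            raise ValueError(f"no samples in the {name} stroke")
        sub = np.flatnonzero(mask)
        best = sub[np.argmax(s[sub])]  # argmax returns first max -> earlier time
        peaks[name] = Peak(value=float(s[best]), time=float(t[best]), index=int(best))
    return PeakPair(s_max1=peaks["downward"], s_max2=peaks["upward"])


def phenotype_map_at(
    frames: list[NodalFieldFrame],
    t_eval: float,
    params: StimulusParams | None = None,
    thresholds: PhenotypeThresholds | None = None,
) -> PhenotypeMap:
    """Classify every node of the frame at ``t_eval``.

    Node-level S uses the node-level fields of that frame (not the surface
    averages, which only select the evaluation time).
    """
    times = np.array([fr.time for fr in frames])
    hits = np.flatnonzero(np.isclose(times, t_eval, rtol=0, atol=1e-9))
    if hits.size == 0:
        raise ValueError(f"t_eval={t_eval} is not a frame time")
    fr = frames[int(hits[0])]
    s = stimulus(fr.oss, fr.wss_mpa, params)
    return PhenotypeMap(labels=classify(s, thresholds), time=fr.time, stimulus=s)


def distribution(
    pmap: PhenotypeMap,
    weighting: str = "node_count",
    node_area: np.ndarray | None = None,
    amplitude_fraction: float | None = None,
) -> PhenotypeDistribution:
    """Surface percentage of each phenotype label.

    ``weighting="node_count"`` treats every node as one cell (the default,
    matching node-per-cell phenotype maps); ``"area"`` weights nodes by
    their surface patch area and requires ``node_area``.
    """
    if pmap.n_nodes == 0:
        raise ValueError("phenotype map is empty")
    if weighting == "node_count":
        w = np.ones(pmap.n_nodes)
    elif weighting == "area":
        if node_area is None:
            raise ValueError("area weighting requires node_area")
        w = np.asarray(node_area, dtype=float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = w.sum()
    pct = {
        lab: float(100.0 * w[pmap.labels == lab].sum() / total) for lab in LABELS
    }
    return PhenotypeDistribution(
        percentages=pct,
        amplitude_fraction=amplitude_fraction,
        time=pmap.time,
        weighting=weighting,
    )


def viability_flags(
    frame: NodalFieldFrame, limits: ViabilityLimits | None = None
) -> pd.DataFrame:
    """Per-node viability diagnostics (purely informational).

    Columns: ``oss_death`` (OSS above the strain-death limit),
    ``wss_apoptosis`` (WSS above the apoptosis stress), ``wss_outside_window``
    (WSS outside the differentiation-compatible range).  Flags never change
    the S-based phenotype classification.
    """
    limits = limits or ViabilityLimits()
    lo, hi = limits.wss_window_mpa
    return pd.DataFrame(
        {
            "oss_death": frame.oss > limits.oss_death,
            "wss_apoptosis": frame.wss_mpa > limits.wss_apoptosis_mpa,
            "wss_outside_window": (frame.wss_mpa < lo) | (frame.wss_mpa > hi),
        }
    )


# ---------------------------------------------------------------------------
# pipeline: reduced-order frames -> peaks -> map -> distribution


def generate_reduced_order_frames(
    mesh: SurfaceMesh,
    protocol: LoadProtocol,
    oss_params: _mech.OssFieldParams | None = None,
    wss_params: _flow.WssFieldParams | None = None,
    props: _flow.FluidProps | None = None,
    seed: int = 0,
) -> list[NodalFieldFrame]:
    """Build the full cycle of nodal OSS/WSS frames from the stand-in models.

    The OSS and WSS node factors use decorrelated child seeds spawned from
    ``seed`` so the two heterogeneity patterns are independent.
    """
    props = props or _flow.FluidProps()
    times = time_grid(protocol)
    e = np.abs(piston_displacement(times, protocol)) / protocol.scaffold_height
    seed_oss, seed_wss = _child_seeds(seed)
    oss = _mech.reduced_order_oss_field(mesh, e, oss_params, seed=seed_oss)
    wss = _flow.reduced_order_wss_field(
        mesh, protocol, mesh.spec, props, wss_params, seed=seed_wss, times=times
    )
    return [
        NodalFieldFrame(time=float(t), oss=oss[i], wss_mpa=wss[i], node_area=mesh.node_area)
        for i, t in enumerate(times)
    ]


def _child_seeds(seed: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    a, b = ss.spawn(2)
    return (
        int(a.generate_state(1)[0] % (2**31)),
        int(b.generate_state(1)[0] % (2**31)),
    )


@dataclass
class AmplitudeResult:
    """Everything computed for one compression amplitude."""

    amplitude_fraction: float
    series: pd.DataFrame
    peaks: PeakPair
    pmap: PhenotypeMap
    dist: PhenotypeDistribution


def run_single_amplitude(
    mesh: SurfaceMesh,
    protocol: LoadProtocol,
    params: StimulusParams | None = None,
    thresholds: PhenotypeThresholds | None = None,
    oss_params: _mech.OssFieldParams | None = None,
    wss_params: _flow.WssFieldParams | None = None,
    props: _flow.FluidProps | None = None,
    seed: int = 0,
    weighting: str = "node_count",
    frames: list[NodalFieldFrame] | None = None,
    evaluate_at: str = "s_max2",
) -> AmplitudeResult:
    """Run the scoring pipeline for one amplitude.

    Frames default to the reduced-order models; pass imported solver frames
    to score external results instead.  ``evaluate_at`` selects the
    evaluation stroke peak (``"s_max2"`` default, ``"s_max1"`` for the
    downstroke comparison).
    """
    if frames is None:
        frames = generate_reduced_order_frames(
            mesh, protocol, oss_params, wss_params, props, seed
        )
    series = s_avg_series(frames, params)
    peaks = detect_peaks(series, protocol)
    peak = peaks.s_max2 if evaluate_at == "s_max2" else peaks.s_max1
    pmap = phenotype_map_at(frames, peak.time, params, thresholds)
    dist = distribution(
        pmap,
        weighting=weighting,
        node_area=mesh.node_area,
        amplitude_fraction=protocol.amplitude_fraction,
    )
    return AmplitudeResult(
        amplitude_fraction=protocol.amplitude_fraction,
        series=series,
        peaks=peaks,
        pmap=pmap,
        dist=dist,
    )


@dataclass
class StudyResult:
    """Amplitude parameter study output."""

    results: list[AmplitudeResult] = field(default_factory=list)

    @property
    def distribution_table(self) -> pd.DataFrame:
        """Long-form table: amplitude_pct, label, percentage."""
        rows = []
        for r in self.results:
            for lab in LABELS:
                rows.append(
                    (100 * r.amplitude_fraction, lab, r.dist.percentages[lab])
                )
        return pd.DataFrame(rows, columns=["amplitude_pct", "label", "percentage"])

    @property
    def peaks_table(self) -> pd.DataFrame:
        rows = [
            (
                100 * r.amplitude_fraction,
                r.peaks.s_max1.value,
                r.peaks.s_max1.time,
                r.peaks.s_max2.value,
                r.peaks.s_max2.time,
            )
            for r in self.results
        ]
        return pd.DataFrame(
            rows,
            columns=["amplitude_pct", "s_max1", "t_s_max1", "s_max2", "t_s_max2"],
        )

    def pivot(self) -> pd.DataFrame:
        return self.distribution_table.pivot(
            index="amplitude_pct", columns="label", values="percentage"
        )[list(LABELS)]


def run_parameter_study(
    amplitudes,
    mesh: SurfaceMesh,
    frequency: float = 1.0,
    dt: float = 0.004,
    n_cycles: int = 1,
    params: StimulusParams | None = None,
    thresholds: PhenotypeThresholds | None = None,
    oss_params: _mech.OssFieldParams | None = None,
    wss_params: _flow.WssFieldParams | None = None,
    props: _flow.FluidProps | None = None,
    seed: int = 0,
    weighting: str = "node_count",
) -> StudyResult:
    """Sweep compression amplitudes through the full scoring pipeline.

    The same seed (hence the same node heterogeneity pattern) is reused for
    every amplitude, so differences across rows reflect the loading alone.
    """
    amplitudes = list(amplitudes)
    if not amplitudes:
        raise ValueError("amplitudes must be nonempty")
    out = StudyResult()
    for a in amplitudes:
        protocol = LoadProtocol(
            frequency=frequency,
            amplitude_fraction=float(a),
            scaffold_height=mesh.spec.height,
            dt=dt,
            n_cycles=n_cycles,
        )
        try:
            res = run_single_amplitude(
                mesh,
                protocol,
                params,
                thresholds,
                oss_params,
                wss_params,
                props,
                seed=seed,
                weighting=weighting,
            )
        except Exception as exc:  # annotate with the offending amplitude
            raise RuntimeError(f"parameter study failed at amplitude {a}") from exc
        out.results.append(res)
    return out
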