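"""Flow-space base calling from per-cluster, per-flow fluorescence traces.

Each flow delivers one nucleotide species; a cluster's trace for that flow
carries the kinetic signature of 0, 1, 2, ... incorporations (longer
homopolymers hold the labelled polymerase on the cluster longer).  The
caller turns traces into features and classifies them into homopolymer
counts:

1. *DC-bias removal*: subtract the mean of the first 40 frames (pre-reagent
   baseline) from each trace.
2. *Windowed integration*: sum the corrected trace over a base-specific
   window tied to incorporation speed (first 150 frames for G and A flows,
   200 for C, 350 for T, at 10 frames/s).
3. *Copy-number normalization*: divide each cluster's integrated counts by
   the summed counts of designated calibration flows, cancelling the
   per-cluster template copy number.
4. *Amplitude features*: maximum amplitude (on a 5-frame moving average) and
   steady-state amplitude (mean of the trailing 50 frames); their ratio is a
   second discrimination axis.
5. *Classification*: bivariate K-means on (MaxAmp/SSAmp ratio, normalized
   counts) pooled per base, or a univariate Gaussian-mixture EM on the
   normalized counts with BIC model selection.  Classes map to homopolymer
   counts by ascending mean normalized counts.
6. *Decoding*: per-flow counts concatenate to a read, clipped to a fixed
   length, with Phred qualities from GMM posteriors where available.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InputError
from .kinetics import max_and_ss_amp

__all__ = [
    "CallerConfig",
    "FlowFeatures",
    "FlowCalls",
    "Read",
    "GmmResult",
    "remove_dc_bias",
    "integrate_flow",
    "compute_features",
    "normalize_by_calibration",
    "call_kmeans",
    "gmm_em_1d",
    "call_gmm_em",
    "call_run",
    "decode_flowgram",
    "decode_run",
    "write_fastq",
]

DEFAULT_WINDOWS = {"G": 150, "A": 150, "C": 200, "T": 350}


@dataclass(frozen=True)
class CallerConfig:
    """Base-caller configuration.

    ``calibration_flows`` are 0-based flow indices (the defaults 6, 11, 19,
    22, 31 are flows 7, 12, 20, 23 and 32 in 1-based counting - flows with a
    significant number of homopolymers on the monotemplate, whose summed
    counts estimate the cluster template number robustly).
    """

    flow_order: str = "GCAT"
    integration_windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    dc_window: int = 40
    calibration_flows: tuple[int, ...] = (6, 11, 19, 22, 31)
    method: Literal["kmeans2d", "gmm1d"] = "kmeans2d"
    max_mer: int = 5
    clip: int = 20
    ss_window: int = 50
    max_smooth_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip < 1:
            raise InputError("clip must be >= 1")
        if any(w < 1 for w in self.integration_windows.values()):
            raise InputError("integration windows must be >= 1 frame")
        if self.dc_window < 1:
            raise InputError("dc_window must be >= 1")

    @property
    def config_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha1(payload).hexdigest()[:10]


@dataclass
class FlowFeatures:
    """Per-cluster, per-flow feature arrays (clusters x flows)."""

    integrated: np.ndarray
    normalized: np.ndarray
    max_amp: np.ndarray
    ss_amp: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray  # (clusters,) bool: calibration sum was positive
    flow_bases: list[str]


@dataclass
class FlowCalls:
    """Integer homopolymer class per cluster per flow, with optional posteriors."""

    classes: np.ndarray  # (clusters, flows) int
    posterior: np.ndarray | None = None  # (clusters, flows) float


@dataclass
class Read:
    sequence: str
    qualities: list[int]
    cluster_id: str
    provenance: dict = field(default_factory=dict)


def remove_dc_bias(trace: np.ndarray, dc_window: int = 40) -> np.ndarray:
    """Subtract the mean of the first ``dc_window`` samples from a trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.size <= dc_window:
        warnings.warn(
            f"trace length {trace.size} <= dc_window {dc_window}; using available prefix"
        )
        dc_window = max(trace.size - 1, 1)
    return trace - trace[:dc_window].mean()


def integrate_flow(trace: np.ndarray, base: str, config: CallerConfig) -> float:
    """Sum a (DC-corrected) trace over the base-specific integration window."""
    trace = np.asarray(trace, dtype=float)
    if base not in config.integration_windows:
        raise InputError(f"no integration window configured for base {base!r}")
    window = config.integration_windows[base]
    if window > trace.size:
        raise InputError(f"window {window} exceeds trace length {trace.size}")
    return float(trace[:window].sum())


def compute_features(
    traces: np.ndarray,
    flow_bases: Sequence[str],
    config: CallerConfig,
) -> FlowFeatures:
    """DC-correct, integrate, normalize and extract amplitude features.

    ``traces`` is (clusters, flows, frames).  The MaxAmp/SSAmp epsilon floor
    is 1e-6 of the run's intensity scale (largest absolute trace value).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 3:
        raise InputError("traces must be (clusters, flows, frames)")
    n_c, n_f, _ = traces.shape
    if len(flow_bases) != n_f:
        raise InputError("flow_bases length must equal the number of flows")
    eps = 1e-6 * max(float(np.max(np.abs(traces))), 1e-30)
    integrated = np.empty((n_c, n_f))
    max_amp = np.empty((n_c, n_f))
    ss_amp = np.empty((n_c, n_f))
    ratio = np.empty((n_c, n_f))
    for c in range(n_c):
        for f in range(n_f):
            corr = remove_dc_bias(traces[c, f], config.dc_window)
            integrated[c, f] = integrate_flow(corr, flow_bases[f], config)
            m, s, r = max_and_ss_amp(
                corr,
                config.ss_window,
                smooth_window=config.max_smooth_window,
                eps=eps,
            )
            max_amp[c, f] = m
            ss_amp[c, f] = s
            ratio[c, f] = r
    feats = FlowFeatures(
        integrated=integrated,
        normalized=np.full_like(integrated, np.nan),
        max_amp=max_amp,
        ss_amp=ss_amp,
        ratio=ratio,
        valid=np.ones(n_c, dtype=bool),
        flow_bases=list(flow_bases),
    )
    return normalize_by_calibration(feats, config.calibration_flows)


def normalize_by_calibration(
    features: FlowFeatures,
    calibration_flows: Sequence[int],
) -> FlowFeatures:
    """Divide each cluster's integrated counts by its calibration-flow sum.

    Renders the counts invariant to per-cluster intensity scale (template
    copy number, illumination).  Clusters whose calibration sum is <= 0 are
    flagged invalid and their normalized counts left NaN.
    """
    calibration_flows = tuple(calibration_flows)
    n_f = features.integrated.shape[1]
    if not calibration_flows or any(not (0 <= i < n_f) for i in calibration_flows):
        raise InputError("calibration flow indices out of range")
    calib = features.integrated[:, list(calibration_flows)].sum(axis=1)
    valid = calib > 0
    if not np.all(valid):
        warnings.warn(
            f"{int((~valid).sum())} cluster(s) with non-positive calibration sum excluded"
        )
    normalized = np.full_like(features.integrated, np.nan)
    normalized[valid] = features.integrated[valid] / calib[valid, None]
    return replace_features(features, normalized=normalized, valid=valid)


def replace_features(features: FlowFeatures, **kwargs) -> FlowFeatures:
    d = dict(
        integrated=features.integrated,
        normalized=features.normalized,
        max_amp=features.max_amp,
        ss_amp=features.ss_amp,
        ratio=features.ratio,
        valid=features.valid,
        flow_bases=features.flow_bases,
    )
    d.update(kwargs)
    return FlowFeatures(**d)


def call_kmeans(
    ratio: np.ndarray,
    normalized: np.ndarray,
    class_values: Sequence[int],
    *,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate K-means homopolymer classification for one base's flows.

    Clusters the (MaxAmp/SSAmp ratio, normalized counts) points into
    ``len(class_values)`` groups (k-means++ with ``n_init`` restarts, fixed
    seed; axes are z-scored first so neither feature dominates).  Groups are
    mapped to ``class_values`` by ascending mean normalized counts.  Returns
    (calls, centroids-in-original-units).  With fewer points than classes, a
    quantile-threshold fallback is used.
    """
    from sklearn.cluster import KMeans

    ratio = np.asarray(ratio, dtype=float).ravel()
    normalized = np.asarray(normalized, dtype=float).ravel()
    if ratio.shape != normalized.shape:
        raise InputError("ratio and normalized must have equal length")
    values = np.asarray(sorted(class_values), dtype=int)
    k = len(values)
    if k == 1:
        return np.full(ratio.size, values[0]), np.array(
            [[ratio.mean(), normalized.mean()]]
        )
    X = np.stack([ratio, normalized], axis=1)
    if ratio.size < k:
        warnings.warn("fewer points than classes: falling back to threshold calling")
        edges = np.linspace(normalized.min(), normalized.max(), k + 1)[1:-1]
        calls = values[np.searchsorted(edges, normalized)]
        return calls, np.full((k, 2), np.nan)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    order = np.argsort(
        [normalized[km.labels_ == j].mean() for j in range(k)], kind="stable"
    )
    relabel = np.empty(k, dtype=int)
    relabel[order] = values
    calls = relabel[km.labels_]
    centroids = km.cluster_centers_[order] * sd + mu
    return calls, centroids


@dataclass
class GmmResult:
    """Fitted 1-D Gaussian mixture with the EM log-likelihood trajectory."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray  # (n, k), components sorted by mean
    log_likelihoods: np.ndarray  # one entry per EM iteration
    bic: float
    variance_floored: bool


def gmm_em_1d(
    x: np.ndarray,
    n_components: int,
    *,
    shared_variance: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
    var_floor_frac: float = 1e-8,
) -> GmmResult:
    """Expectation-maximisation for a univariate Gaussian mixture.

    Deterministic k-means initialisation; with ``shared_variance`` all
    components share one variance (homopolymer classes differ mainly in
    mean).  The log-likelihood is non-decreasing across iterations (EM
    guarantee); a variance floor (``var_floor_frac`` of the data variance)
    guards against components collapsing onto duplicated points.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    k = int(n_components)
    if n < 2 * k:
        raise InputError(f"need at least {2 * k} points for {k} components")
    data_var = max(float(np.var(x)), 1e-300)
    floor = var_floor_frac * data_var
    # k-means initialisation (deterministic seed): robust to very unequal
    # class occupancy, where plain quantile init collapses components onto
    # the dominant level
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(x.reshape(-1, 1))
    means = np.sort(km.cluster_centers_.ravel())
    variances = np.full(k, max(data_var / max(k * k, 1), floor))
    weights = np.full(k, 1.0 / k)
    lls: list[float] = []
    floored = False
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E step
        with np.errstate(divide="ignore"):
            log_pdf = (
                -0.5 * np.log(2 * np.pi * variances)[None, :]
                - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
                + np.log(weights)[None, :]
            )
        m = log_pdf.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = float(log_norm.sum())
        resp = np.exp(log_pdf - log_norm[:, None])
        lls.append(ll)
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol * max(abs(lls[-2]), 1.0):
            break
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        sq = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        if shared_variance:
            v = sq.sum() / n
            if v < floor:
                v, floored = floor, True
            variances = np.full(k, v)
        else:
            variances = sq / nk
            if np.any(variances < floor):
                floored = True
                variances = np.maximum(variances, floor)
    order = np.argsort(means, kind="stable")
    n_params = (k - 1) + k + (1 if shared_variance else k)
    bic = -2.0 * lls[-1] + n_params * np.log(n)
    if floored:
        warnings.warn("GMM variance floor applied (degenerate component)")
    return GmmResult(
        means=means[order],
        variances=variances[order],
        weights=weights[order],
        responsibilities=resp[:, order],
        log_likelihoods=np.array(lls),
        bic=bic,
        variance_floored=floored,
    )


def call_gmm_em(
    normalized: np.ndarray,
    class_values: Sequence[int],
    *,
    shared_variance: bool = True,
    select_bic: bool = True,
) -> tuple[np.ndarray, np.ndarray, GmmResult]:
    """Univariate GMM-EM homopolymer classification for one base's flows.

    Fits mixtures with 1..len(class_values) components and keeps the BIC
    minimiser (or exactly len(class_values) components when ``select_bic``
    is off).  Components are ordered by mean and mapped onto the first
    ``n_components`` entries of the ascending ``class_values``.  Returns
    (calls, posterior-of-assigned-class, fitted model).
    """
    x = np.asarray(normalized, dtype=float).ravel()
    values = np.asarray(sorted(class_values), dtype=int)
    k_max = len(values)
    best: GmmResult | None = None
    ks = range(1, k_max + 1) if select_bic else [k_max]
    for k in ks:
        if x.size < 2 * k:
            break
        fit = gmm_em_1d(x, k, shared_variance=shared_variance)
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise InputError("too few points for even a single Gaussian component")
    labels = np.argmax(best.responsibilities, axis=1)
    calls = values[labels]
    posterior = best.responsibilities[np.arange(x.size), labels]
    return calls, posterior, best


def call_run(
    features: FlowFeatures,
    config: CallerConfig,
    *,
    truth_flowgrams: np.ndarray | None = None,
) -> FlowCalls:
    """Classify every (cluster, flow) of a run, pooled per base.

    All flows of one base are pooled into a single classification problem
    (their normalized counts share the class structure).  With
    ``truth_flowgrams`` given (calibration mode), the candidate class values
    per base are the distinct true counts observed for that base; otherwise
    0..max_mer.  Invalid clusters (no calibration signal) get class -1
    everywhere.
    """
    n_c, n_f = features.normalized.shape
    classes = np.full((n_c, n_f), -1, dtype=int)
    posterior = np.full((n_c, n_f), np.nan)
    valid = features.valid
    bases = np.array(features.flow_bases)
    for base in sorted(set(features.flow_bases)):
        cols = np.nonzero(bases == base)[0]
        pts_norm = features.normalized[np.ix_(valid, cols)].ravel()
        pts_ratio = features.ratio[np.ix_(valid, cols)].ravel()
        if truth_flowgrams is not None:
            # clip at max_mer: longer homopolymers saturate the signal and are
            # indistinguishable from the max class
            class_values = sorted(
                {min(int(v), config.max_mer) for v in truth_flowgrams[:, cols].ravel()}
            )
        else:
            class_values = list(range(config.max_mer + 1))
        if config.method == "kmeans2d":
            calls, _ = call_kmeans(
                pts_ratio, pts_norm, class_values, seed=config.seed
            )
            post = None
        elif config.method == "gmm1d":
            # with known class values (calibration mode) the component count
            # is fixed; BIC selection is for the unknown-class-count case
            calls, post, _ = call_gmm_em(
                pts_norm, class_values, select_bic=truth_flowgrams is None
            )
        else:
            raise InputError(f"unknown calling method {config.method!r}")
        block = calls.reshape(int(valid.sum()), cols.size)
        classes[np.ix_(valid, cols)] = block
        if post is not None:
            posterior[np.ix_(valid, cols)] = post.reshape(block.shape)
    return FlowCalls(
        classes=classes,
        posterior=None if np.all(np.isnan(posterior)) else posterior,
    )


def decode_flowgram(
    calls: np.ndarray,
    flow_bases: Sequence[str],
    clip: int,
    *,
    posteriors: np.ndarray | None = None,
    cluster_id: str = "read",
    provenance: dict | None = None,
    placeholder_quality: int = 20,
) -> Read:
    """Concatenate per-flow homopolymer calls into a clipped read.

    Phred qualities derive from the per-flow class posterior as
    ``-10 log10(1 - p)`` capped at 40 where available, else a fixed
    placeholder (Q20).  An all-zero flowgram yields an empty read (flagged
    in provenance).
    """
    calls = np.asarray(calls)
    if calls.ndim != 1 or len(flow_bases) != calls.size:
        raise InputError("calls must be 1-D and aligned with flow_bases")
    seq_parts: list[str] = []
    quals: list[int] = []
    for f, (n, base) in enumerate(zip(calls, flow_bases)):
        if n <= 0:
            continue
        if posteriors is not None and np.isfinite(posteriors[f]):
            p = min(float(posteriors[f]), 1.0 - 1e-10)
            q = int(min(40, round(-10.0 * np.log10(1.0 - p))))
        else:
            q = placeholder_quality
        seq_parts.append(base * int(n))
        quals.extend([q] * int(n))
    seq = "".join(seq_parts)[:clip]
    quals = quals[: len(seq)]
    prov = dict(provenance or {})
    if not seq:
        prov["empty"] = True
    return Read(sequence=seq, qualities=quals, cluster_id=cluster_id, provenance=prov)


def decode_run(
    calls: FlowCalls,
    flow_bases: Sequence[str],
    config: CallerConfig,
    *,
    ids: Sequence[str] | None = None,
    strip_prefix: str = "",
) -> list[Read]:
    """Decode every cluster of a run into clipped reads.

    ``strip_prefix`` removes a known leading sequence (e.g. the calibration
    sequence of a heterogeneous library) from each decoded read before the
    clip is applied.  Unscored clusters (all calls < 0) yield empty reads.
    """
    n_c = calls.classes.shape[0]
    if ids is None:
        ids = [f"read_{i:05d}" for i in range(n_c)]
    prov = {"method": config.method, "config": config.config_hash}
    reads = []
    for c in range(n_c):
        cls = np.clip(calls.classes[c], 0, None)
        post = calls.posterior[c] if calls.posterior is not None else None
        r = decode_flowgram(
            cls,
            flow_bases,
            clip=len(strip_prefix) + config.clip,
            posteriors=post,
            cluster_id=ids[c],
            provenance=dict(prov),
        )
        if strip_prefix:
            if r.sequence.startswith(strip_prefix):
                r.sequence = r.sequence[len(strip_prefix):]
                r.qualities = r.qualities[len(strip_prefix):]
            else:
                r.provenance["calibration_mismatch"] = True
        r.sequence = r.sequence[: config.clip]
        r.qualities = r.qualities[: config.clip]
        reads.append(r)
    return reads


def write_fastq(reads: Sequence[Read], path) -> int:
    """Write reads as FASTQ (4 lines per record); returns the count written.

    Empty-sequence reads are skipped with a warning reporting the count.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if not reads:
        raise InputError("no reads to write")
    records = []
    skipped = 0
    for r in reads:
        if not r.sequence:
            skipped += 1
            continue
        rec = SeqRecord(Seq(r.sequence), id=r.cluster_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    if skipped:
        warnings.warn(f"skipped {skipped} empty read(s)")
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return len(records)
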