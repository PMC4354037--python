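"""Synthetic sequencing-run generator.

Emulates a kinetics-readout sequencing run on a clustered flow cell: ordered
single-nucleotide flows are delivered to clonal template clusters, and each
cluster's per-flow fluorescence time trace is synthesised from the
mass-action signal-complex model in :mod:`kinflow.kinetics`.  The generator
produces ground-truth flowgrams alongside the traces (and, optionally,
rendered image stacks), so every downstream stage - spot detection, trace
extraction, base calling, alignment - can be validated end to end.

What is emulated: per-flow binding/incorporation kinetics (0..n-mer dwell via
chained incorporation stages), cluster-to-cluster template copy-number
variation (lognormal), loss of synchrony across a cluster's templates
(lag/lead phasing as a per-position probability distribution), camera
background with linear drift, Gaussian read noise and optional shot noise.
What is not: optics (PSF aside), fluidics hydrodynamics, enzyme batch
effects, DNA secondary structure.

Default study conditions mirror the experiments this pipeline targets: a
monotemplate run of 44 flows over ~357 clusters (flow order G,C,A,T) and a
phiX174-like run of 64 flows over heterogeneous fragments (order G,T,A,C,
reads clipped at 20 bp), both imaged at 10 frames/s for 40 s per flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .kinetics import RateConstants, ReactionMix, simulate_timecourse

__all__ = [
    "Flow",
    "FlowProgram",
    "TemplateSet",
    "PhasingParams",
    "NoiseParams",
    "SimulatedRun",
    "SpotLayout",
    "expected_flowgram",
    "apply_phasing",
    "phasing_per_molecule",
    "simulate_cluster_flow_traces",
    "render_flow",
    "render_movie",
    "make_reference",
    "fragment_reference",
    "sequencing_rate_constants",
    "make_monotemplate_run",
    "make_phix_like_run",
    "MONOTEMPLATE_INSERT",
    "CALIBRATION_SEQUENCE",
]

BASES = "ACGT"

#: Insertion sequence of the monotemplate flow cell (read strand).
MONOTEMPLATE_INSERT = (
    "CTAAGTTTTTCACTTAAAGAGGCTTAGGGAAAGTGATTTTTAAAGAGTCACTGTTACATGGTAATATGCCGTTCA"
)

#: Known prefix prepended to heterogeneous-library templates.  Under the
#: G,T,A,C flow order it incorporates exactly one base on each of the first
#: eight flows; flows 1..7 (0-based 0..6) therefore carry exactly seven bases
#: for every cluster and serve as per-cluster calibration flows for
#: copy-number normalization (flow 8 may absorb a leading C-run of the
#: fragment and is excluded from the normalizer).
CALIBRATION_SEQUENCE = "GTACGTAC"

# Sequencing-regime concentrations (uM).  Enzyme is flowed at 150 nM; the
# effective template pool and association rate are calibrated to the same
# 125 1/s pseudo-first-order flux as the theory regime, with the pool sized
# so one incorporation stage completes in a few seconds and graded
# homopolymer dwell fits the base-calling integration windows.
SEQ_ENZYME_TOTAL = 0.15
SEQ_DNA_TOTAL = 1.5
_SEQ_FLUX = 125.0

#: Homopolymer runs longer than this are simulated with this many chained
#: incorporation stages (dwell growth is sub-linear and the integration
#: window caps the signal anyway).
MAX_CHAIN = 5


def sequencing_rate_constants(
    k_off_dna: float = 500.0,
    *,
    k_pol: float = 9.0,
    kd_app_nt: float = 30.0,
    k_on_nt: float = 100.0,
    mismatch_kd_app_nt: float = 1e4,
    mismatch_specificity: float = 4.6e-6,
) -> tuple[RateConstants, RateConstants]:
    """(correct, mismatch) rate constants for the on-flow-cell regime."""
    k_on_dna = _SEQ_FLUX / SEQ_DNA_TOTAL
    correct = RateConstants.from_kd(
        k_on_dna=k_on_dna,
        k_off_dna=k_off_dna,
        k_pol=k_pol,
        kd_app_nt=kd_app_nt,
        k_on_nt=k_on_nt,
    )
    mismatch = RateConstants.from_kd(
        k_on_dna=k_on_dna,
        k_off_dna=k_off_dna,
        k_pol=mismatch_specificity * mismatch_kd_app_nt,
        kd_app_nt=mismatch_kd_app_nt,
        k_on_nt=k_on_nt,
    )
    return correct, mismatch


@dataclass(frozen=True)
class Flow:
    base: str
    concentration: float = 100.0  # uM

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise InputError(f"flow base must be one of {BASES}, got {self.base!r}")
        if self.concentration <= 0:
            raise ParameterError("flow nucleotide concentration must be > 0")


@dataclass(frozen=True)
class FlowProgram:
    """Ordered nucleotide flows with imaging parameters.

    ``dead_frames`` frames at the start of each flow precede reagent arrival
    (pumping delay); they image pure background and are what the DC-bias
    window of the base caller averages over.
    """

    flows: tuple[Flow, ...]
    frames_per_flow: int = 400
    frame_rate: float = 10.0  # Hz
    dead_frames: int = 40

    def __post_init__(self) -> None:
        if len(self.flows) < 1:
            raise InputError("need at least one flow")
        if self.frame_rate <= 0:
            raise ParameterError("frame rate must be > 0")
        if not (0 <= self.dead_frames < self.frames_per_flow):
            raise ParameterError("require 0 <= dead_frames < frames_per_flow")

    @classmethod
    def cyclic(
        cls,
        order: str,
        n_flows: int,
        *,
        concentrations: Mapping[str, float] | float = 100.0,
        frames_per_flow: int = 400,
        frame_rate: float = 10.0,
        dead_frames: int = 40,
    ) -> "FlowProgram":
        """Repeat ``order`` cyclically for ``n_flows`` flows."""
        if isinstance(concentrations, Mapping):
            conc = dict(concentrations)
        else:
            conc = {b: float(concentrations) for b in BASES}
        flows = tuple(
            Flow(order[i % len(order)], conc[order[i % len(order)]]) for i in range(n_flows)
        )
        return cls(
            flows=flows,
            frames_per_flow=frames_per_flow,
            frame_rate=frame_rate,
            dead_frames=dead_frames,
        )

    @property
    def bases(self) -> list[str]:
        return [f.base for f in self.flows]


@dataclass(frozen=True)
class TemplateSet:
    """Template sequences (5'->3' read order) with per-cluster copy numbers."""

    sequences: tuple[str, ...]
    copy_numbers: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        cn = np.asarray(self.copy_numbers, dtype=float)
        object.__setattr__(self, "copy_numbers", cn)
        if not (len(self.sequences) == cn.size == len(self.ids)):
            raise InputError("sequences, copy_numbers and ids must have equal length")
        if np.any(cn <= 0):
            raise InputError("copy numbers must be > 0")
        for s in self.sequences:
            if not s or any(c not in BASES for c in s):
                raise InputError("templates must be non-empty strings over ACGT")

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def uniform(cls, sequence: str, n_clusters: int, copy_number: float = 1.0) -> "TemplateSet":
        return cls(
            sequences=(sequence,) * n_clusters,
            copy_numbers=np.full(n_clusters, copy_number),
            ids=tuple(f"cluster_{i:05d}" for i in range(n_clusters)),
        )


@dataclass(frozen=True)
class PhasingParams:
    """Per-flow loss-of-synchrony probabilities.

    ``p_lag``: probability a template fails to extend on a flow it should
    (incomplete extension); ``p_lead``: probability a template advances one
    base on a flow it should not (read-forward / misincorporation).
    """

    p_lag: float = 0.0
    p_lead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_lag", "p_lead"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} must be in [0, 1), got {v!r}")


@dataclass(frozen=True)
class NoiseParams:
    """Detector and illumination noise model.

    ``photon_scale``: counts per unit %SC per template copy; ``background``:
    constant camera offset (counts); ``background_drift``: additional counts
    added linearly over each flow; ``read_noise_sigma``: Gaussian read noise;
    ``shot_noise``: Poisson-resample each sample.
    """

    photon_scale: float = 1000.0
    background: float = 100.0
    background_drift: float = 0.0
    read_noise_sigma: float = 0.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        for name in ("photon_scale", "background", "background_drift", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class SimulatedRun:
    """Traces, ground truth and provenance of one simulated run."""

    traces: np.ndarray  # (clusters, flows, frames)
    truth_flowgrams: np.ndarray  # (clusters, flows) int
    templates: TemplateSet
    program: FlowProgram
    phasing: PhasingParams
    noise: NoiseParams
    seed: int
    rates_correct: RateConstants
    rates_mismatch: RateConstants

    def trace_table(self) -> pd.DataFrame:
        """Long-format table: cluster x flow rows, frame columns."""
        n_c, n_f, n_t = self.traces.shape
        idx = pd.MultiIndex.from_product(
            [list(self.templates.ids), range(n_f)], names=["cluster", "flow"]
        )
        return pd.DataFrame(self.traces.reshape(n_c * n_f, n_t), index=idx)


def _homopolymer_length(sequence: str, pos: int, base: str) -> int:
    n = 0
    while pos + n < len(sequence) and sequence[pos + n] == base:
        n += 1
    return n


def expected_flowgram(sequence: str, flow_order: Sequence[str] | str, n_flows: int) -> np.ndarray:
    """Integer incorporation counts per flow under perfect synchrony.

    ``flow_order`` is either a cyclic base order (repeated to cover
    ``n_flows``) or an explicit per-flow base list of length >= n_flows.
    Each flow incorporates the full pending homopolymer of its base.
    """
    if not sequence:
        raise InputError("sequence must be non-empty")
    if any(c not in BASES for c in sequence):
        raise InputError("sequence contains characters outside ACGT")
    order = list(flow_order)
    if any(b not in BASES for b in order):
        raise InputError("flow order contains characters outside ACGT")
    if len(order) >= n_flows:
        flows = order[:n_flows]
    else:
        flows = [order[i % len(order)] for i in range(n_flows)]
    counts = np.zeros(n_flows, dtype=int)
    pos = 0
    for f, base in enumerate(flows):
        n = _homopolymer_length(sequence, pos, base)
        counts[f] = n
        pos += n
    return counts


def apply_phasing(
    distribution: np.ndarray,
    template: str,
    base: str,
    phasing: PhasingParams,
) -> np.ndarray:
    """Advance a per-position probability distribution through one flow.

    ``distribution[p]`` is the fraction of the cluster's templates whose next
    unsequenced base is ``template[p]`` (index ``len(template)`` = finished).
    Mass at a matching position advances by the full homopolymer length with
    probability ``1 - p_lag``; mass at a non-matching position advances one
    base with probability ``p_lead``.
    """
    dist = np.asarray(distribution, dtype=float)
    L = len(template)
    if dist.shape != (L + 1,):
        raise InputError("distribution must have length len(template) + 1")
    if not np.isclose(dist.sum(), 1.0, atol=1e-9):
        raise InputError("distribution must sum to 1")
    out = np.zeros_like(dist)
    for p in range(L + 1):
        m = dist[p]
        if m == 0.0:
            continue
        run = _homopolymer_length(template, p, base) if p < L else 0
        if run > 0:
            out[p] += phasing.p_lag * m
            out[p + run] += (1.0 - phasing.p_lag) * m
        elif p < L:
            out[p] += (1.0 - phasing.p_lead) * m
            out[p + 1] += phasing.p_lead * m
        else:
            out[p] += m
    return out


def phasing_per_molecule(
    template: str,
    flow_bases: Sequence[str],
    phasing: PhasingParams,
    n_molecules: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo per-molecule reference for :func:`apply_phasing`.

    Samples individual template molecules through the flow sequence and
    returns the empirical position distribution.  Intended for validating the
    matrix update at small n; the matrix form is exact in expectation.
    """
    rng = np.random.default_rng(seed)
    L = len(template)
    pos = np.zeros(n_molecules, dtype=int)
    for base in flow_bases:
        for i in range(n_molecules):
            p = pos[i]
            run = _homopolymer_length(template, p, base) if p < L else 0
            if run > 0:
                if rng.random() >= phasing.p_lag:
                    pos[i] = p + run
            elif p < L:
                if rng.random() < phasing.p_lead:
                    pos[i] = p + 1
    return np.bincount(pos, minlength=L + 1) / n_molecules


class _BasisCache:
    """Per-(concentration, n-mer) signal-complex traces for the flow regime."""

    def __init__(
        self,
        rates_correct: RateConstants,
        rates_mismatch: RateConstants,
        t_grid: np.ndarray,
        enzyme_total: float = SEQ_ENZYME_TOTAL,
        dna_total: float = SEQ_DNA_TOTAL,
    ) -> None:
        self.rates_correct = rates_correct
        self.rates_mismatch = rates_mismatch
        self.t_grid = t_grid
        self.enzyme_total = enzyme_total
        self.dna_total = dna_total
        self._cache: dict[tuple[float, int], np.ndarray] = {}

    def percent_sc(self, concentration: float, n_mer: int) -> np.ndarray:
        n_mer = min(n_mer, MAX_CHAIN)
        key = (float(concentration), n_mer)
        if key not in self._cache:
            mix = ReactionMix(
                enzyme_total=self.enzyme_total,
                dna_total=self.dna_total,
                nucleotide=float(concentration),
                is_correct=n_mer > 0,
            )
            if n_mer == 0:
                tc = simulate_timecourse(
                    self.rates_mismatch, mix, self.t_grid, n_incorporations=1, mode="flow"
                )
            else:
                tc = simulate_timecourse(
                    self.rates_correct, mix, self.t_grid, n_incorporations=n_mer, mode="flow"
                )
            self._cache[key] = tc.percent_sc_series
        return self._cache[key]


def simulate_cluster_flow_traces(
    templates: TemplateSet,
    program: FlowProgram,
    rates: tuple[RateConstants, RateConstants] | None = None,
    phasing: PhasingParams = PhasingParams(),
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
) -> SimulatedRun:
    """Simulate per-cluster per-flow fluorescence traces with ground truth.

    For each cluster a probability distribution over template positions is
    carried through the flow program.  On each flow the population splits
    into sub-fractions whose pending homopolymer length for the flowed base
    is n = 0, 1, 2, ...; the cluster's kinetic signal is the mixture of the
    corresponding n-mer signal-complex time courses, scaled by photon scale
    and template copy number, plus background and noise.  Ground-truth
    flowgrams are recorded from the phasing-free walk.
    """
    if rates is None:
        rates = sequencing_rate_constants()
    rates_correct, rates_mismatch = rates
    rng = np.random.default_rng(seed)
    n_clusters = len(templates)
    n_flows = len(program.flows)
    frames = program.frames_per_flow
    live = frames - program.dead_frames
    t_grid = np.arange(live) / program.frame_rate
    basis = _BasisCache(rates_correct, rates_mismatch, t_grid)

    traces = np.zeros((n_clusters, n_flows, frames), dtype=float)
    truth = np.zeros((n_clusters, n_flows), dtype=int)

    frame_idx = np.arange(frames)
    drift = noise.background_drift * frame_idx / max(frames - 1, 1)

    for c, seq in enumerate(templates.sequences):
        truth[c] = expected_flowgram(seq, program.bases, n_flows)
        dist = np.zeros(len(seq) + 1)
        dist[0] = 1.0
        cn = templates.copy_numbers[c]
        for f, flow in enumerate(program.flows):
            # split the population by pending homopolymer length for this base
            frac: dict[int, float] = {}
            for p in np.nonzero(dist)[0]:
                n = _homopolymer_length(seq, p, flow.base) if p < len(seq) else 0
                frac[n] = frac.get(n, 0.0) + dist[p]
            signal = np.zeros(live)
            for n, m in frac.items():
                if m > 0:
                    signal += m * basis.percent_sc(flow.concentration, n)
            tr = np.full(frames, noise.background, dtype=float) + drift
            tr[program.dead_frames:] += noise.photon_scale * cn * signal
            if noise.shot_noise:
                tr = rng.poisson(np.clip(tr, 0, None)).astype(float)
            if noise.read_noise_sigma > 0:
                tr += rng.normal(0.0, noise.read_noise_sigma, size=frames)
            traces[c, f] = tr
            dist = apply_phasing(dist, seq, flow.base, phasing)
    return SimulatedRun(
        traces=traces,
        truth_flowgrams=truth,
        templates=templates,
        program=program,
        phasing=phasing,
        noise=noise,
        seed=seed,
        rates_correct=rates_correct,
        rates_mismatch=rates_mismatch,
    )


@dataclass(frozen=True)
class SpotLayout:
    """Cluster positions and point-spread function for movie rendering."""

    centers: np.ndarray  # (n, 2) float (row, col)
    image_shape: tuple[int, int]
    psf_sigma: float = 1.2  # px

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if self.psf_sigma <= 0:
            raise ParameterError("psf_sigma must be > 0")
        h, w = self.image_shape
        if np.any(c[:, 0] < 0) or np.any(c[:, 0] >= h) or np.any(c[:, 1] < 0) or np.any(c[:, 1] >= w):
            raise InputError("spot centers must lie inside the image bounds")

    @classmethod
    def grid(
        cls, n_spots: int, *, pitch: int = 7, margin: int = 6, psf_sigma: float = 1.2
    ) -> "SpotLayout":
        """Regular grid layout large enough for ``n_spots`` clusters."""
        per_side = int(np.ceil(np.sqrt(n_spots)))
        size = 2 * margin + (per_side - 1) * pitch + 1
        rows, cols = np.divmod(np.arange(n_spots), per_side)
        centers = np.stack([margin + rows * pitch, margin + cols * pitch], axis=1).astype(float)
        return cls(centers=centers, image_shape=(size, size), psf_sigma=psf_sigma)


def _psf_matrix(layout: SpotLayout) -> "np.ndarray":
    """Sparse (pixels x spots) matrix of unit-amplitude Gaussian footprints."""
    from scipy import sparse

    h, w = layout.image_shape
    sig = layout.psf_sigma
    half = int(np.ceil(4 * sig))
    rows, cols, vals = [], [], []
    for s, (r0, c0) in enumerate(layout.centers):
        rr = np.arange(max(0, int(r0) - half), min(h, int(r0) + half + 1))
        cc = np.arange(max(0, int(c0) - half), min(w, int(c0) + half + 1))
        g = np.exp(
            -((rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2) / (2 * sig**2)
        )
        pix = (rr[:, None] * w + cc[None, :]).ravel()
        rows.extend(pix.tolist())
        cols.extend([s] * pix.size)
        vals.extend(g.ravel().tolist())
    return sparse.csr_matrix((vals, (rows, cols)), shape=(h * w, len(layout.centers)))


def render_flow(
    run: SimulatedRun,
    layout: SpotLayout,
    flow: int,
    seed: int = 0,
    *,
    dtype=np.float32,
    _psf: "np.ndarray | None" = None,
) -> np.ndarray:
    """Render the image stack of one flow (frames, rows, cols).

    Each frame is ``background + sum_c trace[c, frame] * PSF_c`` where the
    per-cluster traces already include the run's photon scale and background
    level; the rendered background is the run's background level so that
    off-spot pixels match the trace baseline.  Poisson/Gaussian noise follows
    the run's noise parameters, drawn from a per-flow substream of ``seed``
    so flows can be rendered independently (and streamed, which keeps memory
    flat for large runs).
    """
    if layout.centers.shape[0] != run.traces.shape[0]:
        raise InputError("layout must have one center per cluster")
    rng = np.random.default_rng([seed, flow])
    M = _psf_matrix(layout) if _psf is None else _psf
    h, w = layout.image_shape
    amp = run.traces[:, flow, :] - run.noise.background  # spot signal above background
    flat = M @ amp  # (pixels, frames)
    stack = flat.T.reshape(run.traces.shape[2], h, w) + run.noise.background
    if run.noise.shot_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if run.noise.read_noise_sigma > 0:
        stack = stack + rng.normal(0.0, run.noise.read_noise_sigma, size=stack.shape)
    return stack.astype(dtype)


def render_movie(
    run: SimulatedRun,
    layout: SpotLayout,
    seed: int = 0,
    *,
    dtype=np.float32,
) -> list[np.ndarray]:
    """Render one image stack per flow; see :func:`render_flow`.

    Holds every stack in memory - for large runs iterate :func:`render_flow`
    instead.  Stacks are float arrays writable as multi-frame TIFF via
    :func:`tifffile.imwrite`.
    """
    # identical centers would silently sum; warn per contract
    uniq = np.unique(layout.centers, axis=0)
    if uniq.shape[0] < layout.centers.shape[0]:
        import warnings

        warnings.warn("overlapping identical spot centers: signals are summed")
    M = _psf_matrix(layout)
    return [
        render_flow(run, layout, f, seed, dtype=dtype, _psf=M)
        for f in range(run.traces.shape[1])
    ]


def make_reference(length: int, base_composition: Sequence[float], seed: int) -> str:
    """Random reference sequence with the given A/C/G/T composition."""
    p = np.asarray(base_composition, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or p.sum() <= 0:
        raise InputError("base_composition must be 4 non-negative weights with positive sum")
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length, p=p))


_COMPL = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def fragment_reference(
    sequence: str,
    insert_length: int,
    n: int,
    seed: int,
    *,
    both_strands: bool = True,
    prefix: str = "",
) -> TemplateSet:
    """Draw ``n`` random fragments (either strand) as a template set.

    ``prefix`` (e.g. the calibration sequence) is prepended to every
    fragment's read strand.
    """
    if len(sequence) <= insert_length:
        raise InputError("reference must be longer than the insert length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(sequence) - insert_length + 1, size=n)
    seqs = []
    for s in starts:
        frag = sequence[s : s + insert_length]
        if both_strands and rng.random() < 0.5:
            frag = reverse_complement(frag)
        seqs.append(prefix + frag)
    return TemplateSet(
        sequences=tuple(seqs),
        copy_numbers=np.ones(n),
        ids=tuple(f"frag_{i:05d}" for i in range(n)),
    )


def lognormal_copy_numbers(n: int, cv: float, seed: int) -> np.ndarray:
    """Lognormal copy numbers with mean 1 and the given coefficient of variation."""
    sigma2 = np.log(1.0 + cv**2)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def make_monotemplate_run(
    seed: int,
    *,
    n_clusters: int = 357,
    n_flows: int = 44,
    order: str = "GCAT",
    copy_number_cv: float = 0.3,
    phasing: PhasingParams = PhasingParams(),
    noise: NoiseParams = NoiseParams(),
    k_off_dna: float = 500.0,
) -> SimulatedRun:
    """Monotemplate emulation: one insert sequence on every cluster.

    Defaults follow the monotemplate experiment: 44 flows in G,C,A,T order
    over ~357 clusters, 10 frames/s for 40 s per flow.  (The alternative
    printed order G,T,A,C is available via ``order``.)
    """
    templates = TemplateSet(
        sequences=(MONOTEMPLATE_INSERT,) * n_clusters,
        copy_numbers=lognormal_copy_numbers(n_clusters, copy_number_cv, seed + 1),
        ids=tuple(f"cluster_{i:05d}" for i in range(n_clusters)),
    )
    program = FlowProgram.cyclic(order, n_flows)
    return simulate_cluster_flow_traces(
        templates,
        program,
        rates=sequencing_rate_constants(k_off_dna),
        phasing=phasing,
        noise=noise,
        seed=seed,
    )


def make_phix_like_run(
    seed: int,
    *,
    reference: str | None = None,
    reference_length: int = 5000,
    n_clusters: int = 5000,
    n_flows: int = 64,
    order: str = "GTAC",
    insert_length: int = 60,
    copy_number_cv: float = 0.3,
    phasing: PhasingParams = PhasingParams(),
    noise: NoiseParams = NoiseParams(),
    k_off_dna: float = 500.0,
) -> tuple[SimulatedRun, str]:
    """Heterogeneous-library emulation against a (phiX174-sized) reference.

    Each cluster carries a random fragment of the reference (either strand)
    prefixed with :data:`CALIBRATION_SEQUENCE` so that the first flows give a
    per-cluster copy-number calibration.  Returns the run and the reference.
    """
    if reference is None:
        reference = make_reference(reference_length, (0.25, 0.25, 0.25, 0.25), seed + 2)
    templates = fragment_reference(
        reference,
        insert_length,
        n_clusters,
        seed + 3,
        prefix=CALIBRATION_SEQUENCE,
    )
    templates = TemplateSet(
        sequences=templates.sequences,
        copy_numbers=lognormal_copy_numbers(n_clusters, copy_number_cv, seed + 4),
        ids=templates.ids,
    )
    program = FlowProgram.cyclic(order, n_flows)
    run = simulate_cluster_flow_traces(
        templates,
        program,
        rates=sequencing_rate_constants(k_off_dna),
        phasing=phasing,
        noise=noise,
        seed=seed,
    )
    return run, reference
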