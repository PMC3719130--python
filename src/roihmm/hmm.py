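"""Discrete hidden-Markov species-vocalization models.

A species vocalization is modelled as a sequence of notes: a hidden
Markov model lambda = (A, B, pi) with a left-to-right state topology
(one state per note type, transitions only to self or the next state).
Observations are discrete symbols obtained by quantizing each candidate
ROI's (min_freq_hz, bandwidth_hz, duration_s) through a per-feature
uniform-bin codebook; maximum intensity is deliberately excluded from
the symbol because it depends on gain and distance to the animal.

Training: the user supplies example ROI series (e.g. "two chirps
followed by a shrill").  Initial A and B come from aligning every
example uniformly across the states and counting transitions/emissions
(Laplace +1 smoothed, then row-normalised); pi is concentrated on state
0.  Baum-Welch (multi-sequence, scaled forward-backward) then
re-estimates A', B', pi' to a local likelihood maximum.

Detection: candidate ROIs of a recording are filtered by per-feature
ranges, tokenized in time order, and every contiguous window whose
length lies within the training-sequence length range is scored by the
forward algorithm.  The decision score is the best length-normalised
log-likelihood; a recording is called present when the score reaches
the model's decision threshold (default: minimum normalised training
score minus one standard deviation).  There is no randomness anywhere:
training and detection are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HMMParams",
    "Codebook",
    "ObservationSequence",
    "SpeciesModel",
    "DetectionRecord",
    "FEATURES",
    "build_codebook",
    "apply_filter",
    "assemble_sequences",
    "init_model",
    "baum_welch",
    "log_likelihood",
    "detect",
    "train_model",
]

#: the ROI features that form the observation symbol, in radix order
FEATURES = ("min_freq_hz", "bandwidth_hz", "duration_s")

_ROW_TOL = 1e-9


@dataclass
class HMMParams:
    """lambda = (A, B, pi): transition, emission and initial probabilities."""

    a: np.ndarray   # [N x N] state transitions
    b: np.ndarray   # [N x M] symbol emissions given state
    pi: np.ndarray  # [N] initial state distribution

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        self.pi = np.asarray(self.pi, dtype=np.float64)
        n = self.pi.size
        if self.a.shape != (n, n):
            raise ValueError(f"A must be [{n}x{n}], got {self.a.shape}")
        if self.b.ndim != 2 or self.b.shape[0] != n:
            raise ValueError(f"B must have {n} rows, got {self.b.shape}")
        for name, arr in (("A", self.a), ("B", self.b)):
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > _ROW_TOL):
                raise ValueError(f"rows of {name} must sum to 1")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > _ROW_TOL:
            raise ValueError("pi must be a probability vector")

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_symbols(self) -> int:
        return self.b.shape[1]

    def copy(self) -> "HMMParams":
        return HMMParams(self.a.copy(), self.b.copy(), self.pi.copy())


@dataclass
class Codebook:
    """Quantizer from ROI features to a discrete symbol alphabet.

    Each feature has uniform bin edges spanning the training range; the
    outer bins are open so out-of-range values still map to a symbol.
    The symbol index is the mixed-radix combination of the per-feature
    bin indices, so the alphabet size M is the product of bin counts.
    """

    edges: tuple[np.ndarray, ...]  # one strictly increasing edge array per feature

    def __post_init__(self) -> None:
        self.edges = tuple(np.asarray(e, dtype=np.float64) for e in self.edges)
        if len(self.edges) != len(FEATURES):
            raise ValueError(f"need one edge array per feature in {FEATURES}")
        for e in self.edges:
            if e.size < 2 or np.any(np.diff(e) < 0):
                raise ValueError("edges must be non-decreasing with >= 2 entries")

    @property
    def bins_per_feature(self) -> tuple[int, ...]:
        return tuple(e.size - 1 for e in self.edges)

    @property
    def n_symbols(self) -> int:
        return int(np.prod(self.bins_per_feature))

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        """Map rows of a feature table to symbol indices."""
        symbol = np.zeros(len(table), dtype=np.int64)
        for feat, e in zip(FEATURES, self.edges):
            nb = e.size - 1
            idx = np.searchsorted(e, table[feat].to_numpy(), side="right") - 1
            idx = np.clip(idx, 0, nb - 1)  # outer bins are open
            symbol = symbol * nb + idx
        return symbol


@dataclass
class ObservationSequence:
    """Tokenized candidate ROIs of one recording, in time order."""

    symbols: np.ndarray
    recording_id: str = ""
    roi_indices: np.ndarray | None = None

    def __len__(self) -> int:
        return self.symbols.size


@dataclass
class DetectionRecord:
    """Presence decision for one (recording, species) pair."""

    recording_id: str
    species: str
    score: float
    present: bool
    timestamp: object = None  # tz-aware datetime when known


def build_codebook(
    records: pd.DataFrame,
    bins_per_feature: Sequence[int] = (8, 8, 8),
) -> Codebook:
    """Uniform per-feature bin edges over the training feature ranges.

    Raises
    ------
    ValueError
        If ``records`` is empty.
    """
    if len(records) == 0:
        raise ValueError("cannot build a codebook from an empty training set")
    edges = []
    for feat, nb in zip(FEATURES, bins_per_feature):
        v = records[feat].to_numpy(dtype=np.float64)
        lo, hi = float(v.min()), float(v.max())
        edges.append(np.linspace(lo, hi, int(nb) + 1))
    return Codebook(tuple(edges))


def apply_filter(
    table: pd.DataFrame,
    candidate_filter: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Keep ROIs whose features fall inside the per-feature [low, high] ranges."""
    keep = np.ones(len(table), dtype=bool)
    for feat, (lo, hi) in candidate_filter.items():
        if lo > hi:
            raise ValueError(f"filter for {feat} has low {lo} > high {hi}")
        v = table[feat].to_numpy(dtype=np.float64)
        keep &= (v >= lo) & (v <= hi)
    return table.loc[keep]


def assemble_sequences(
    roi_table: pd.DataFrame,
    codebook: Codebook,
    candidate_filter: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, ObservationSequence]:
    """One observation sequence per recording in ``roi_table``.

    ROIs failing the candidate filter are dropped; survivors are
    tokenized sorted by start time (ties broken by minimum frequency).
    Recordings whose ROIs are all filtered out yield empty sequences.
    """
    out: dict[str, ObservationSequence] = {}
    for rec_id, group in roi_table.groupby("recording_id", sort=True):
        if candidate_filter:
            group = apply_filter(group, candidate_filter)
        group = group.sort_values(["t_start_s", "min_freq_hz"], kind="stable")
        symbols = codebook.encode(group)
        indices = (group["roi_index"].to_numpy()
                   if "roi_index" in group else None)
        out[str(rec_id)] = ObservationSequence(symbols, str(rec_id), indices)
    return out


def init_model(
    n_states: int,
    sequences: Iterable[ObservationSequence | np.ndarray],
    n_symbols: int,
) -> HMMParams:
    """Initial lambda from uniform alignment of the training sequences.

    Topology is left-to-right: state i may transition only to itself or
    i+1 (last state only to itself), and pi is concentrated on state 0.
    Position t of a length-T sequence is assigned to state
    floor(t * N / T); transition and emission counts from these
    alignments are Laplace-smoothed (+1 on the allowed entries) and
    row-normalised.
    """
    if n_states < 1:
        raise ValueError(f"n_states must be >= 1, got {n_states}")
    seqs = [np.asarray(getattr(s, "symbols", s), dtype=np.int64)
            for s in sequences]
    seqs = [s for s in seqs if s.size > 0]
    if not seqs:
        raise ValueError("all training sequences are empty")
    for s in seqs:
        if s.min() < 0 or s.max() >= n_symbols:
            raise ValueError(f"symbol out of range [0, {n_symbols})")

    n, m = n_states, n_symbols
    a_counts = np.zeros((n, n))
    b_counts = np.zeros((n, m))
    for s in seqs:
        t = s.size
        states = (np.arange(t) * n) // t  # uniform alignment
        np.add.at(b_counts, (states, s), 1.0)
        np.add.at(a_counts, (states[:-1], states[1:]), 1.0)

    allowed = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    allowed[idx, idx] = True
    allowed[idx[:-1], idx[:-1] + 1] = True
    a = np.where(allowed, a_counts + 1.0, 0.0)
    a /= a.sum(axis=1, keepdims=True)
    b = b_counts + 1.0
    b /= b.sum(axis=1, keepdims=True)
    pi = np.zeros(n)
    pi[0] = 1.0
    return HMMParams(a, b, pi)


def _forward(params: HMMParams, symbols: np.ndarray):
    """Scaled forward pass; returns (scaled alphas, scale factors).

    A zero scale factor means the sequence has probability zero under
    the model (log-likelihood -inf).
    """
    a, b, pi = params.a, params.b, params.pi
    t_len = symbols.size
    alphas = np.zeros((t_len, params.n_states))
    scales = np.zeros(t_len)
    alpha = pi * b[:, symbols[0]]
    for t in range(t_len):
        if t > 0:
            alpha = (alpha @ a) * b[:, symbols[t]]
        c = alpha.sum()
        scales[t] = c
        if c == 0.0:
            return alphas, scales  # impossible sequence
        alpha = alpha / c
        alphas[t] = alpha
    return alphas, scales


def log_likelihood(params: HMMParams, sequence: ObservationSequence | np.ndarray) -> float:
    """Exact log P(O | lambda) by the scaled forward algorithm.

    Returns -inf for a sequence the model assigns probability zero.

    Raises
    ------
    ValueError
        If the sequence is empty or contains an out-of-range symbol.
    """
    symbols = np.asarray(getattr(sequence, "symbols", sequence), dtype=np.int64)
    if symbols.size == 0:
        raise ValueError("log-likelihood of an empty sequence is undefined")
    if symbols.min() < 0 or symbols.max() >= params.n_symbols:
        raise ValueError(
            f"symbol out of range [0, {params.n_symbols}) in sequence")
    _, scales = _forward(params, symbols)
    if np.any(scales == 0.0):
        return -np.inf
    return float(np.log(scales).sum())


def baum_welch(
    params: HMMParams,
    sequences: Iterable[ObservationSequence | np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[HMMParams, list[float]]:
    """Multi-sequence Baum-Welch re-estimation of (A, B, pi).

    Iterates expectation-maximisation until the relative improvement of
    the total log-likelihood falls below ``tol`` or ``max_iter`` is
    reached.  Structural zeros of A (and pi) are preserved, so a
    left-to-right model stays left-to-right.  Returns the re-estimated
    parameters and the per-iteration total log-likelihood trace
    (non-decreasing, up to round-off).
    """
    seqs = [np.asarray(getattr(s, "symbols", s), dtype=np.int64)
            for s in sequences]
    seqs = [s for s in seqs if s.size > 0]
    if not seqs:
        raise ValueError("all training sequences are empty")
    for s in seqs:
        if s.min() < 0 or s.max() >= params.n_symbols:
            raise ValueError(
                f"symbol out of range [0, {params.n_symbols}) in training data")

    params = params.copy()
    n, m = params.n_states, params.n_symbols
    history: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        a, b, pi = params.a, params.b, params.pi
        a_num = np.zeros((n, n))
        b_num = np.zeros((n, m))
        gamma_sum = np.zeros(n)       # over t = 1..T-1 (transition denominator)
        gamma_total = np.zeros(n)     # over all t (emission denominator)
        pi_num = np.zeros(n)
        total_ll = 0.0
        for s in seqs:
            alphas, scales = _forward(params, s)
            if np.any(scales == 0.0):
                total_ll = -np.inf
                continue
            total_ll += float(np.log(scales).sum())
            t_len = s.size
            betas = np.zeros((t_len, n))
            beta = np.ones(n)
            betas[-1] = beta
            for t in range(t_len - 2, -1, -1):
                beta = a @ (b[:, s[t + 1]] * beta) / scales[t + 1]
                betas[t] = beta
            gamma = alphas * betas
            gamma /= gamma.sum(axis=1, keepdims=True)
            pi_num += gamma[0]
            gamma_total += gamma.sum(axis=0)
            if t_len > 1:
                gamma_sum += gamma[:-1].sum(axis=0)
                # xi_t[i, j] = alpha_t[i] a[i,j] b[j, o_{t+1}] beta_{t+1}[j] / c_{t+1}
                obs_beta = b[:, s[1:]].T * betas[1:]          # [T-1 x N]
                xi = np.einsum("ti,tj->ij", alphas[:-1],
                               obs_beta / scales[1:, None])
                a_num += a * xi
            np.add.at(b_num.T, s, gamma)  # emission counts per symbol
        history.append(total_ll)
        if not np.isfinite(total_ll):
            break

        new_a = params.a.copy()
        nz = gamma_sum > 0
        new_a[nz] = a_num[nz] / gamma_sum[nz, None]
        # renormalise to absorb round-off
        rows = new_a.sum(axis=1, keepdims=True)
        new_a = np.where(rows > 0, new_a / rows, params.a)
        new_b = params.b.copy()
        nzb = gamma_total > 0
        new_b[nzb] = b_num[nzb] / gamma_total[nzb, None]
        new_pi = pi_num / len(seqs)
        new_pi /= new_pi.sum()
        params = HMMParams(new_a, new_b, new_pi)

        if prev_ll > -np.inf:
            denom = max(abs(prev_ll), 1.0)
            if (total_ll - prev_ll) / denom < tol:
                break
        prev_ll = total_ll
    return params, history


@dataclass
class SpeciesModel:
    """A trained species/vocalization detector.

    Bundles the HMM parameters with everything needed to apply them to
    new recordings: the feature codebook, the per-feature candidate
    ranges that select which ROIs enter the observation sequence, the
    window-length bounds (from training-sequence lengths), and the
    decision threshold on the length-normalised log-likelihood.
    """

    species: str
    params: HMMParams
    codebook: Codebook
    candidate_filter: dict[str, tuple[float, float]]
    decision_threshold: float
    min_window: int
    max_window: int
    n_states: int
    min_span_s: float = 0.0     # shortest admissible window time span
    max_span_s: float = np.inf  # longest admissible window time span
    training_scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.min_window < 1 or self.max_window < self.min_window:
            raise ValueError("invalid window-length bounds")
        for feat, (lo, hi) in self.candidate_filter.items():
            if lo > hi:
                raise ValueError(f"candidate_filter for {feat}: low > high")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_states": self.n_states,
            "a": self.params.a.tolist(),
            "b": self.params.b.tolist(),
            "pi": self.params.pi.tolist(),
            "codebook_edges": [e.tolist() for e in self.codebook.edges],
            "candidate_filter": {k: list(v) for k, v in self.candidate_filter.items()},
            "decision_threshold": self.decision_threshold,
            "min_window": self.min_window,
            "max_window": self.max_window,
            "min_span_s": self.min_span_s,
            "max_span_s": None if np.isinf(self.max_span_s) else self.max_span_s,
            "training_scores": list(self.training_scores),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesModel":
        return cls(
            species=d["species"],
            params=HMMParams(np.array(d["a"]), np.array(d["b"]), np.array(d["pi"])),
            codebook=Codebook(tuple(np.array(e) for e in d["codebook_edges"])),
            candidate_filter={k: (float(v[0]), float(v[1]))
                              for k, v in d["candidate_filter"].items()},
            decision_threshold=float(d["decision_threshold"]),
            min_window=int(d["min_window"]),
            max_window=int(d["max_window"]),
            min_span_s=float(d.get("min_span_s", 0.0)),
            max_span_s=(np.inf if d.get("max_span_s") is None
                        else float(d["max_span_s"])),
            n_states=int(d["n_states"]),
            training_scores=[float(x) for x in d.get("training_scores", [])],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SpeciesModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _best_window_score(
    model: SpeciesModel,
    symbols: np.ndarray,
    t_start: np.ndarray | None = None,
    t_end: np.ndarray | None = None,
) -> float:
    """Max length-normalised log-likelihood over admissible windows.

    A window is admissible when its length lies within the training
    range and (when ROI times are available) its time span — last
    member's end minus first member's start — lies within the model's
    span bounds.  The notes of one call occupy a characteristic
    stretch of time: spurious symbol runs are typically either spread
    over seconds (independent noise events) or packed into a few tens
    of milliseconds (fragments of one broadband transient).
    """
    best = -np.inf
    t = symbols.size
    for length in range(model.min_window, model.max_window + 1):
        if length > t:
            break
        for start in range(t - length + 1):
            if t_start is not None:
                span = t_end[start + length - 1] - t_start[start]
                if span > model.max_span_s or span < model.min_span_s:
                    continue
            ll = log_likelihood(model.params, symbols[start:start + length])
            score = ll / length
            if score > best:
                best = score
    return best


def detect(
    model: SpeciesModel,
    roi_table: pd.DataFrame,
    recording_id: str | None = None,
    timestamp=None,
) -> DetectionRecord:
    """Score one recording's ROI table and call presence/absence.

    Candidate ROIs are filtered and tokenized; every contiguous window
    of the sequence with length within the training range is scored and
    the best normalised score is compared to the decision threshold.  A
    recording with no candidate ROIs (or none forming an admissible
    window) is absent with score -inf.
    """
    if recording_id is None:
        ids = (roi_table["recording_id"].unique()
               if len(roi_table) and "recording_id" in roi_table else [])
        recording_id = str(ids[0]) if len(ids) else ""
    table = roi_table
    if len(table):
        table = apply_filter(table, model.candidate_filter)
        table = table.sort_values(["t_start_s", "min_freq_hz"], kind="stable")
        symbols = model.codebook.encode(table)
        t0 = table["t_start_s"].to_numpy(dtype=np.float64)
        t1 = table["t_end_s"].to_numpy(dtype=np.float64)
    else:
        symbols = np.empty(0, dtype=np.int64)
        t0 = t1 = None
    score = (_best_window_score(model, symbols, t0, t1)
             if symbols.size else -np.inf)
    present = bool(score >= model.decision_threshold)
    return DetectionRecord(recording_id=str(recording_id), species=model.species,
                           score=float(score), present=present,
                           timestamp=timestamp)


def train_model(
    examples: Sequence[pd.DataFrame],
    n_states: int,
    species: str = "",
    bins_per_feature: Sequence[int] = (8, 8, 8),
    filter_margin: float = 0.10,
    threshold_sds: float = 1.0,
    emission_floor: float = 0.0,
    intensity_floor_factor: float | None = None,
    candidate_filter: Mapping[str, tuple[float, float]] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SpeciesModel:
    """Train a species model from labelled example ROI series.

    Each example is an ordered ROI feature table for one occurrence of
    the target vocalization (e.g. the three ROIs of "two chirps followed
    by a shrill").  The codebook and the candidate-filter ranges are
    derived from the pooled training features (ranges widened by
    ``filter_margin`` of each feature's span); the decision threshold is
    the minimum normalised training score minus ``threshold_sds``
    standard deviations of the training scores.

    ``emission_floor`` mixes the trained emission rows with the uniform
    distribution, ``B <- (1-f) B + f/M``, so a single never-seen symbol
    degrades a window's score instead of vetoing it — useful when the
    quantized features of real detections jitter around the training
    values.  ``intensity_floor_factor``, when given, adds a
    ``max_intensity`` lower bound of ``factor * min(training
    intensities)`` to the candidate filter: bright vocalizations are
    separated from the sea of faint noise events before sequencing.
    Both are applied before the training scores (hence the threshold)
    are computed.
    """
    examples = [e for e in examples if len(e) > 0]
    if not examples:
        raise ValueError("no non-empty training examples")
    if not 0.0 <= emission_floor < 1.0:
        raise ValueError("emission_floor must be in [0, 1)")
    pooled = pd.concat(examples, ignore_index=True)
    codebook = build_codebook(pooled, bins_per_feature)

    if candidate_filter is None:
        candidate_filter = {}
        for feat in FEATURES:
            v = pooled[feat].to_numpy(dtype=np.float64)
            lo, hi = float(v.min()), float(v.max())
            pad = filter_margin * max(hi - lo, np.finfo(float).eps)
            candidate_filter[feat] = (lo - pad, hi + pad)
        if intensity_floor_factor is not None:
            floor = intensity_floor_factor * float(pooled["max_intensity"].min())
            candidate_filter["max_intensity"] = (floor, np.inf)
    else:
        candidate_filter = {k: (float(v[0]), float(v[1]))
                            for k, v in candidate_filter.items()}

    sequences = [ObservationSequence(codebook.encode(
        e.sort_values(["t_start_s", "min_freq_hz"], kind="stable")))
        for e in examples]
    params0 = init_model(n_states, sequences, codebook.n_symbols)
    params, _ = baum_welch(params0, sequences, tol=tol, max_iter=max_iter)
    if emission_floor > 0.0:
        m = params.n_symbols
        params = HMMParams(params.a,
                           (1.0 - emission_floor) * params.b + emission_floor / m,
                           params.pi)

    scores = [log_likelihood(params, s) / len(s) for s in sequences]
    finite = [s for s in scores if np.isfinite(s)]
    if not finite:
        raise ValueError("model assigns zero probability to all training examples")
    # operating point: lower decile of the training scores (one poorly
    # selected example should not drag it down), extended so that a
    # detection in which a single note was degraded to the emission
    # floor — a noise cluster or transient wrecked its bounding box —
    # still passes, minus a spread-based slack
    lengths = [len(s) for s in sequences]
    q10 = float(np.quantile(finite, 0.1))
    base = q10
    if emission_floor > 0.0:
        log_floor = float(np.log(emission_floor / codebook.n_symbols))
        base = q10 + (log_floor - q10) / min(lengths)
    threshold = base - threshold_sds * float(np.std(finite))
    spans = [float(e["t_end_s"].max() - e["t_start_s"].min()) for e in examples]
    return SpeciesModel(
        species=species,
        params=params,
        codebook=codebook,
        candidate_filter=dict(candidate_filter),
        decision_threshold=float(threshold),
        min_window=min(lengths),
        max_window=max(lengths),
        min_span_s=0.5 * min(spans),
        max_span_s=1.5 * max(spans),
        n_states=n_states,
        training_scores=[float(s) for s in scores],
    )
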