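"""Thermodynamic occupancy model: PWM scanning with one free concentration.

A sequence's predicted net occupancy is the sum of fractional site
occupancies gamma*K/(1 + gamma*K) over every window on both strands, where
K is the PWM odds ratio of the window against a background distribution and
gamma is the single free concentration parameter, fitted against normalized
ChIP scores by least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scoring import ScoreTable, normalize_scores

__all__ = [
    "PWM",
    "StapModel",
    "StapTrainingSet",
    "site_affinity",
    "occupancy",
    "fit_gamma",
    "crossval_stap",
    "stap_score_table",
    "read_pwm_file",
    "write_pwm_file",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over (A, C, G, T).

    ``probs`` is L x 4 with rows summing to 1. ``pseudocount`` is added to
    every probability before forming odds ratios (avoids zero affinities);
    ``background`` defaults to the uniform distribution.
    """

    name: str
    probs: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PWM probs must be L x 4 with L >= 1")
        if np.any(probs < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 log odds; column 4 is the ambiguity base N (odds 1)."""
        p = self.probs + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):  # zero prob at pseudocount 0 -> -inf
            lo = np.log(p) - np.log(self.background)[None, :]
        return np.hstack([lo, np.zeros((len(self), 1))])

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class StapModel:
    """A PWM plus its fitted non-negative concentration parameter.

    ``alpha`` and ``beta`` are the affine calibration mapping raw occupancy
    onto the training-target scale (the model's prediction is
    alpha + beta * occupancy); they carry no additional shape freedom.
    """

    pwm: PWM
    gamma: float
    alpha: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gamma >= 0 and math.isfinite(self.gamma)):
            raise ValueError("gamma must be finite and >= 0")


@dataclass
class StapTrainingSet:
    """Sequences with normalized ChIP targets and positive/negative provenance."""

    sequences: list[str]
    targets: np.ndarray
    positive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if len(self.sequences) != self.targets.size:
            raise ValueError("sequences and targets must have equal length")
        if self.targets.size and (
            self.targets.min() < 0 or self.targets.max() > 1
        ):
            raise ValueError("targets must lie in [0,1]")
        if self.positive is None:
            self.positive = np.ones(self.targets.size, dtype=bool)
        else:
            self.positive = np.asarray(self.positive, dtype=bool)

    def __len__(self) -> int:
        return len(self.sequences)


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; N (or any other IUPAC code) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def site_affinity(pwm: PWM, window: str) -> float:
    """Relative affinity K of one L-mer: product of per-position odds ratios.

    N contributes factor 1 at its position. The consensus window maximizes K.
    """
    enc = encode_sequence(window)
    if enc.size != len(pwm):
        raise ValueError(f"window length {enc.size} != motif length {len(pwm)}")
    lo = pwm.log_odds
    return float(np.exp(lo[np.arange(len(pwm)), enc].sum()))


def window_log_affinities(pwm: PWM, seq: str) -> np.ndarray:
    """log K for every window on both strands; shape (2, n_windows).

    Row 0 is the forward strand, row 1 the reverse complement read at the
    same window positions.
    """
    enc = encode_sequence(seq)
    L = len(pwm)
    if enc.size < L:
        raise ValueError(f"sequence length {enc.size} < motif length {L}")
    lo = pwm.log_odds
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    fwd = lo[np.arange(L)[None, :], windows].sum(axis=1)
    # reverse strand: complement and reverse each window
    rc = np.where(enc < 4, _COMPLEMENT[np.minimum(enc, 3)], 4)
    windows_rc = np.lib.stride_tricks.sliding_window_view(rc, L)[:, ::-1]
    rev = lo[np.arange(L)[None, :], windows_rc].sum(axis=1)
    return np.vstack([fwd, rev])


def occupancy(model: StapModel, seq: str) -> float:
    """Expected bound-TF count: sum of gamma*K/(1+gamma*K) over all sites.

    Bounded by 2*(len(seq)-L+1); 0 at gamma=0; non-decreasing in gamma.
    """
    logk = window_log_affinities(model.pwm, seq)
    return _occupancy_from_logk(logk, model.gamma)


def _occupancy_from_logk(logk: np.ndarray, gamma: float) -> float:
    if gamma == 0.0:
        return 0.0
    # q = gK/(1+gK) computed stably via the logistic of log(g)+logK
    z = math.log(gamma) + logk
    with np.errstate(over="ignore"):
        q = np.where(
            z > 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z))
        )
    return float(q.sum())


def _occupancies(logks: list[np.ndarray], gamma: float) -> np.ndarray:
    return np.array([_occupancy_from_logk(lk, gamma) for lk in logks])


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi > lo:
        return (v - lo) / (hi - lo)
    return np.zeros_like(v)


def _affine_sse(occ: np.ndarray, targets: np.ndarray) -> tuple[float, float, float]:
    """Least-squares a + b*occ fit of the targets; returns (sse, a, b), b >= 0."""
    var = float(np.var(occ))
    if var <= 0.0:
        a = float(targets.mean())
        d = targets - a
        return float(d @ d), a, 0.0
    b = float(np.cov(occ, targets, bias=True)[0, 1]) / var
    if b < 0.0:
        b = 0.0
    a = float(targets.mean() - b * occ.mean())
    d = a + b * occ - targets
    return float(d @ d), a, b


def fit_gamma(train: StapTrainingSet, pwm: PWM) -> StapModel:
    """Fit the concentration by least squares against the normalized targets.

    The objective is sum((a + b*occupancy(gamma) - target)^2) with the
    affine calibration (a, b>=0) solved in closed form per gamma — the
    scale of occupancy is not identifiable from correlation-style targets,
    so only gamma carries model shape. Deterministic: a coarse log-scale
    grid over gamma in [1e-6, 1e6] refined by golden-section search.

    Raises
    ------
    ValueError
        If the targets are constant ("uninformative training set").
    """
    targets = train.targets
    if np.unique(targets).size < 2:
        raise ValueError("uninformative training set: constant targets")
    logks = [window_log_affinities(pwm, s) for s in train.sequences]

    def sse_at(loggamma: float) -> float:
        occ = _occupancies(logks, math.exp(loggamma))
        return _affine_sse(occ, targets)[0]

    grid = np.linspace(math.log(1e-6), math.log(1e6), 49)
    losses = [sse_at(g) for g in grid]
    j = int(np.argmin(losses))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    loggamma = _golden_section(sse_at, lo, hi, tol=1e-6)
    gamma = math.exp(loggamma)
    _, a, b = _affine_sse(_occupancies(logks, gamma), targets)
    return StapModel(pwm=pwm, gamma=gamma, alpha=a, beta=b)


def _golden_section(f, a: float, b: float, tol: float) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def predict_scores(model: StapModel, sequences: list[str]) -> np.ndarray:
    """Calibrated occupancy (alpha + beta*occ) of each sequence."""
    logks = [window_log_affinities(model.pwm, s) for s in sequences]
    return model.alpha + model.beta * _occupancies(logks, model.gamma)


def crossval_stap(
    train: StapTrainingSet, pwm: PWM, k: int = 4
) -> tuple[float, list[float], np.ndarray]:
    """k-fold cross-validation of the concentration fit.

    Sequences are split into k contiguous folds; each fold is scored by a
    model fitted on the remainder. Returns the Pearson correlation of the
    aggregated out-of-fold predictions against the targets, the per-fold
    gamma values, and the predictions themselves.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    n = len(train)
    if k > n:
        raise ValueError("more folds than samples")
    from .metrics import pearson_with_pvalue

    bounds = np.linspace(0, n, k + 1).astype(int)
    preds = np.empty(n)
    gammas: list[float] = []
    logks = [window_log_affinities(pwm, s) for s in train.sequences]
    for i in range(k):
        test = np.arange(bounds[i], bounds[i + 1])
        tr = np.setdiff1d(np.arange(n), test)
        sub = StapTrainingSet(
            sequences=[train.sequences[j] for j in tr],
            targets=train.targets[tr],
            positive=train.positive[tr],
        )
        model = fit_gamma(sub, pwm)
        gammas.append(model.gamma)
        occ = _occupancies([logks[j] for j in test], model.gamma)
        preds[test] = model.alpha + model.beta * occ  # training-fold calibration
    r = pearson_with_pvalue(preds, train.targets).r
    return r, gammas, preds


def stap_score_table(
    models: dict[str, StapModel],
    sequences: dict[str, str],
    ids: list[str],
    species: str = "",
) -> ScoreTable:
    """Occupancy of every enhancer under every condition's model, normalized.

    Normalization (cap at mu+3*sigma then min-max) is applied per column,
    the same rule used for ChIP and accessibility scores.
    """
    missing = [i for i in ids if i not in sequences]
    if missing:
        raise ValueError(f"missing sequence for enhancer(s): {missing[:5]}")
    conditions = list(models)
    values = np.empty((len(ids), len(conditions)))
    logk_cache: dict[int, list[np.ndarray]] = {}  # distinct PWMs scanned once
    for j, cond in enumerate(conditions):
        model = models[cond]
        key = id(model.pwm)
        if key not in logk_cache:
            logk_cache[key] = [
                window_log_affinities(model.pwm, sequences[i]) for i in ids
            ]
        values[:, j] = _occupancies(logk_cache[key], model.gamma)
    raw = ScoreTable(
        ids=list(ids), columns=conditions, values=values, species=species
    )
    table, _ = normalize_scores(raw)
    return table


# ---------------------------------------------------------------------------
# PWM file format: '>name' header then 4 whitespace-delimited rows (A,C,G,T)
# ---------------------------------------------------------------------------


def read_pwm_file(path) -> dict[str, PWM]:
    pwms: dict[str, PWM] = {}
    name = None
    rows: list[list[float]] = []

    def flush():
        if name is not None:
            mat = np.array(rows, dtype=float)
            if mat.shape[0] != 4:
                raise ValueError(f"PWM {name!r}: expected 4 rows, got {mat.shape[0]}")
            pwms[name] = PWM(name=name, probs=mat.T)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return pwms


def write_pwm_file(pwms: dict[str, PWM], path) -> None:
    with open(path, "w") as fh:
        for name, pwm in pwms.items():
            fh.write(f">{name}\n")
            for row in pwm.probs.T:  # 4 rows: A, C, G, T
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")
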