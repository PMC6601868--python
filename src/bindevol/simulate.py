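"""Synthetic orthologous-enhancer cohorts with known generative structure.

Emulates a two-species developmental regulatory dataset: ~2,754 orthologous
enhancer pairs, ChIP scores for 14 TF:time-point conditions over five
mesodermal factors (Twi, Tin, Mef2, Bap, Bin) and five time points,
DNase-style accessibility at three time points in both species, and three
mutually exclusive activity classes (Meso, VM, SM) assigned by a known rule
from the ChIP profile. Every latent quantity (planted occupancy, true
concentration, noiseless interspecies binding change) is retained so that
recovery can be tested.

Generative model
----------------
* Species-1 sequences are i.i.d. uniform background with motif matches
  planted from each TF's PWM (Poisson-distributed count per enhancer);
  species-2 sequences are species-1 mutated at a per-bp substitution rate.
* Accessibility is a latent AR(1) Gaussian over the five time points
  (temporally proximal time points stay correlated), perturbed between
  species by an independent Gaussian, and squashed to (0,1) by a logistic.
* ChIP signal = w_occ * normalized thermodynamic occupancy of the species'
  own sequence + w_acc * accessibility at the matching time point, plus
  Gaussian noise, then outlier-capped and min-max normalized per condition.
* The activity label is the class whose rule conditions have the largest
  mean normalized ChIP, provided its margin over the runner-up exceeds
  ``label_margin`` (ambiguous enhancers stay unlabeled, mirroring the
  exclusion of multi-class enhancers).

A single global seed drives a hierarchical RNG: each enhancer owns a
spawned child stream, so any subset of pairs is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scoring import (
    GenomicInterval,
    ScoreTable,
    SignalTrack,
    normalize_scores,
    read_bed,
    read_bedgraph,
    read_score_tsv,
    write_bed,
    write_bedgraph,
    write_score_tsv,
)
from .stap import PWM, StapModel, read_pwm_file, write_pwm_file
from .stap import _occupancies, window_log_affinities  # internal reuse

__all__ = [
    "TIME_POINTS",
    "ACC_TIME_POINTS",
    "DEFAULT_CONDITIONS",
    "DEFAULT_ACTIVITY_RULE",
    "ACTIVITY_CLASSES",
    "EnhancerPair",
    "SimulationConfig",
    "SyntheticCohort",
    "CohortTruth",
    "default_pwms",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

TIME_POINTS = (1, 2, 3, 4, 5)
ACC_TIME_POINTS = (1, 3, 5)  # accessibility assayed at three stages only

# 14 TF:time-point conditions shared between the species: Twi TP1-3,
# Tin TP2-3, Mef2 TP1-5, Bap TP3, Bin TP3-5 (Tin:TP1 is unavailable).
DEFAULT_CONDITIONS: tuple[str, ...] = (
    "Twi:TP1",
    "Twi:TP2",
    "Twi:TP3",
    "Tin:TP2",
    "Tin:TP3",
    "Mef2:TP1",
    "Mef2:TP2",
    "Mef2:TP3",
    "Mef2:TP4",
    "Mef2:TP5",
    "Bap:TP3",
    "Bin:TP3",
    "Bin:TP4",
    "Bin:TP5",
)

ACTIVITY_CLASSES = ("Meso", "VM", "SM")

# class -> conditions whose mean ChIP defines membership: early Twi/Tin
# binding marks unspecified mesoderm, mid-embryogenesis Bap (the
# visceral-muscle selector) defines VM, late Mef2/Bin somatic muscle.
# VM rests on a single condition so its class score keeps variance
# comparable to the temporally peripheral classes.
DEFAULT_ACTIVITY_RULE: dict[str, tuple[str, ...]] = {
    "Meso": ("Twi:TP1", "Twi:TP2", "Tin:TP2"),
    "VM": ("Bap:TP3",),
    "SM": ("Mef2:TP4", "Mef2:TP5", "Bin:TP5"),
}

_CONSENSI = {
    "Twi": "CACATGTG",  # E-box CANNTG core
    "Tin": "TCAAGTGG",  # NK-2 class
    "Mef2": "CTATTTAT",  # AT-rich MADS box
    "Bap": "TTAAGTGC",
    "Bin": "TGTTTACA",  # forkhead class
}


def default_pwms(strength: float = 0.85) -> dict[str, PWM]:
    """Informative length-8 PWMs for the five factors.

    Each position puts ``strength`` probability on the consensus base and
    splits the remainder over the other three.
    """
    pwms = {}
    for tf, cons in _CONSENSI.items():
        L = len(cons)
        probs = np.full((L, 4), (1.0 - strength) / 3.0)
        for i, b in enumerate(cons):
            probs[i, "ACGT".index(b)] = strength
        pwms[tf] = PWM(name=tf, probs=probs)
    return pwms


def condition_tf(cond: str) -> str:
    return cond.split(":")[0]


def condition_tp(cond: str) -> int:
    return int(cond.split(":TP")[1])


@dataclass(frozen=True)
class EnhancerPair:
    """An orthologous enhancer pair: shared id, two intervals, two sequences."""

    id: str
    interval_mel: GenomicInterval
    interval_vir: GenomicInterval
    seq_mel: str
    seq_vir: str


@dataclass
class SimulationConfig:
    """Parameters of the generative model (defaults are the study conditions)."""

    n_pairs: int = 2754
    seq_length: int = 1000
    per_tf_pwm: dict[str, PWM] = field(default_factory=default_pwms)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    site_density: float = 2.0
    substitution_rate: float = 0.13
    accessibility_autocorr: float = 0.7
    acc_divergence_sd: float = 0.6
    chip_weights: tuple[float, float] = (0.55, 0.45)  # (w_occ, w_acc)
    chip_noise_sd: float = 0.08
    true_gamma: float = 0.1
    activity_rule: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_RULE)
    )
    label_margin: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")
        for name in ("substitution_rate", "accessibility_autocorr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("acc_divergence_sd", "chip_noise_sd", "site_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.per_tf_pwm:
            raise ValueError("need at least one PWM")
        longest = max(len(p) for p in self.per_tf_pwm.values())
        if self.seq_length < longest:
            raise ValueError(
                f"seq_length {self.seq_length} shorter than longest motif {longest}"
            )
        tfs = set(self.per_tf_pwm)
        for cond in self.conditions:
            if condition_tf(cond) not in tfs:
                raise ValueError(f"condition {cond} has no PWM")
        for cls, conds in self.activity_rule.items():
            for cond in conds:
                if cond not in self.conditions:
                    raise ValueError(f"activity rule for {cls} uses unknown {cond}")


@dataclass
class CohortTruth:
    """Ground-truth latents retained for recovery tests."""

    gamma: dict[str, float]
    occupancy_mel: np.ndarray  # n x n_tf raw thermodynamic occupancies
    occupancy_vir: np.ndarray
    tf_order: list[str]
    acc_latent_mel: np.ndarray  # n x 5 AR(1) latents (pre-logistic)
    acc_latent_vir: np.ndarray
    true_dchip: ScoreTable  # noiseless signal difference, mel - vir


@dataclass
class SyntheticCohort:
    """A generated two-species cohort plus its ground truth."""

    config: SimulationConfig
    pairs: list[EnhancerPair]
    chip_mel: ScoreTable
    chip_vir: ScoreTable
    acc_mel: ScoreTable
    acc_vir: ScoreTable
    acc_raw_mel: ScoreTable
    acc_raw_vir: ScoreTable
    labels: dict[str, str]
    truth: CohortTruth | None = None

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pairs]

    def sequences(self, species: str) -> dict[str, str]:
        if species == "mel":
            return {p.id: p.seq_mel for p in self.pairs}
        if species == "vir":
            return {p.id: p.seq_vir for p in self.pairs}
        raise ValueError(f"unknown species {species!r}")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model. Deterministic in cfg.seed."""
    cfg.validate()
    n = cfg.n_pairs
    tfs = list(cfg.per_tf_pwm)
    n_tf = len(tfs)
    rho = cfg.accessibility_autocorr
    w_occ, w_acc = cfg.chip_weights

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(n)

    seqs_mel = np.empty((n, cfg.seq_length), dtype=np.uint8)
    seqs_vir = np.empty((n, cfg.seq_length), dtype=np.uint8)
    acc_lat_mel = np.empty((n, 5))
    acc_lat_vir = np.empty((n, 5))
    noise_mel = np.empty((n, len(cfg.conditions)))
    noise_vir = np.empty((n, len(cfg.conditions)))

    for i in range(n):
        rng = np.random.default_rng(children[i])
        seq = rng.integers(0, 4, size=cfg.seq_length, dtype=np.uint8)
        for tf in tfs:
            pwm = cfg.per_tf_pwm[tf]
            L = len(pwm)
            for _ in range(rng.poisson(cfg.site_density)):
                pos = int(rng.integers(0, cfg.seq_length - L + 1))
                site = np.array(
                    [rng.choice(4, p=pwm.probs[k]) for k in range(L)],
                    dtype=np.uint8,
                )
                seq[pos : pos + L] = site
        seqs_mel[i] = seq
        mut = rng.random(cfg.seq_length) < cfg.substitution_rate
        shifted = (seq + rng.integers(1, 4, size=cfg.seq_length)) % 4
        seqs_vir[i] = np.where(mut, shifted, seq)

        a = np.empty(5)
        a[0] = rng.normal()
        for t in range(1, 5):
            a[t] = rho * a[t - 1] + np.sqrt(max(1.0 - rho * rho, 0.0)) * rng.normal()
        acc_lat_mel[i] = a
        acc_lat_vir[i] = a + rng.normal(0.0, cfg.acc_divergence_sd, size=5)
        noise_mel[i] = rng.normal(0.0, cfg.chip_noise_sd, size=len(cfg.conditions))
        noise_vir[i] = rng.normal(0.0, cfg.chip_noise_sd, size=len(cfg.conditions))

    ids = [f"enh{i:05d}" for i in range(n)]
    mel_strs = ["".join("ACGT"[b] for b in row) for row in seqs_mel]
    vir_strs = ["".join("ACGT"[b] for b in row) for row in seqs_vir]

    spacing = cfg.seq_length + 200
    pairs = [
        EnhancerPair(
            id=ids[i],
            interval_mel=GenomicInterval(
                "chrSim", i * spacing + 100, i * spacing + 100 + cfg.seq_length,
                ids[i], "mel",
            ),
            interval_vir=GenomicInterval(
                "chrSim", i * spacing + 100, i * spacing + 100 + cfg.seq_length,
                ids[i], "vir",
            ),
            seq_mel=mel_strs[i],
            seq_vir=vir_strs[i],
        )
        for i in range(n)
    ]

    # latent thermodynamic occupancy of each species' own sequence
    occ_mel = np.zeros((n, n_tf))
    occ_vir = np.zeros((n, n_tf))
    for j, tf in enumerate(tfs):
        pwm = cfg.per_tf_pwm[tf]
        if n:
            occ_mel[:, j] = _occupancies(
                [window_log_affinities(pwm, s) for s in mel_strs], cfg.true_gamma
            )
            occ_vir[:, j] = _occupancies(
                [window_log_affinities(pwm, s) for s in vir_strs], cfg.true_gamma
            )

    # pooled min-max per TF so occupancy differences survive normalization
    occ_norm_mel = np.zeros_like(occ_mel)
    occ_norm_vir = np.zeros_like(occ_vir)
    for j in range(n_tf):
        pooled = np.concatenate([occ_mel[:, j], occ_vir[:, j]]) if n else np.array([])
        if pooled.size and pooled.max() > pooled.min():
            lo, hi = pooled.min(), pooled.max()
            occ_norm_mel[:, j] = (occ_mel[:, j] - lo) / (hi - lo)
            occ_norm_vir[:, j] = (occ_vir[:, j] - lo) / (hi - lo)

    acc_mel_all = _logistic(acc_lat_mel)
    acc_vir_all = _logistic(acc_lat_vir)

    tf_index = {tf: j for j, tf in enumerate(tfs)}
    signal_mel = np.zeros((n, len(cfg.conditions)))
    signal_vir = np.zeros((n, len(cfg.conditions)))
    for c, cond in enumerate(cfg.conditions):
        j = tf_index[condition_tf(cond)]
        t = condition_tp(cond) - 1
        signal_mel[:, c] = w_occ * occ_norm_mel[:, j] + w_acc * acc_mel_all[:, t]
        signal_vir[:, c] = w_occ * occ_norm_vir[:, j] + w_acc * acc_vir_all[:, t]

    chip_mel = _normalized_table(
        ids, list(cfg.conditions), signal_mel + noise_mel, "mel"
    )
    chip_vir = _normalized_table(
        ids, list(cfg.conditions), signal_vir + noise_vir, "vir"
    )

    acc_cols = [f"Acc:TP{t}" for t in ACC_TIME_POINTS]
    acc_raw_mel = ScoreTable(
        ids=ids, columns=acc_cols,
        values=acc_mel_all[:, [t - 1 for t in ACC_TIME_POINTS]] if n else np.zeros((0, 3)),
        species="mel",
    )
    acc_raw_vir = ScoreTable(
        ids=ids, columns=acc_cols,
        values=acc_vir_all[:, [t - 1 for t in ACC_TIME_POINTS]] if n else np.zeros((0, 3)),
        species="vir",
    )
    acc_mel_t = _normalized_table(ids, acc_cols, acc_raw_mel.values, "mel")
    acc_vir_t = _normalized_table(ids, acc_cols, acc_raw_vir.values, "vir")

    truth = CohortTruth(
        gamma={tf: cfg.true_gamma for tf in tfs},
        occupancy_mel=occ_mel,
        occupancy_vir=occ_vir,
        tf_order=tfs,
        acc_latent_mel=acc_lat_mel,
        acc_latent_vir=acc_lat_vir,
        true_dchip=ScoreTable(
            ids=ids, columns=list(cfg.conditions),
            values=signal_mel - signal_vir, species="mel-vir",
        ),
    )

    labels = _assign_labels(chip_mel, cfg.activity_rule, cfg.label_margin)

    return SyntheticCohort(
        config=cfg,
        pairs=pairs,
        chip_mel=chip_mel,
        chip_vir=chip_vir,
        acc_mel=acc_mel_t,
        acc_vir=acc_vir_t,
        acc_raw_mel=acc_raw_mel,
        acc_raw_vir=acc_raw_vir,
        labels=labels,
        truth=truth,
    )


def _normalized_table(ids, columns, values, species) -> ScoreTable:
    if len(ids) == 0:
        return ScoreTable(
            ids=[], columns=list(columns),
            values=np.zeros((0, len(columns))), species=species, normalized=True,
        )
    raw = ScoreTable(ids=list(ids), columns=list(columns),
                     values=np.asarray(values, dtype=float), species=species)
    table, _ = normalize_scores(raw)
    return table


def _assign_labels(
    chip_mel: ScoreTable,
    rule: dict[str, tuple[str, ...]],
    margin: float,
) -> dict[str, str]:
    classes = list(rule)
    if not chip_mel.ids:
        return {}
    scores = np.column_stack(
        [
            np.mean([chip_mel.column(c) for c in rule[cls]], axis=0)
            for cls in classes
        ]
    )
    labels: dict[str, str] = {}
    for i, eid in enumerate(chip_mel.ids):
        order = np.argsort(scores[i])[::-1]
        if scores[i, order[0]] - scores[i, order[1]] >= margin:
            labels[eid] = classes[order[0]]
    return labels


# ---------------------------------------------------------------------------
# on-disk cohort layout (all plain text)
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir) -> list[Path]:
    """Write a cohort as FASTA/BED/bedGraph/TSV/PWM files; returns the paths."""
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out}: {exc}") from exc
    written: list[Path] = []

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    for sp in ("mel", "vir"):
        recs = [
            SeqRecord(
                Seq(p.seq_mel if sp == "mel" else p.seq_vir),
                id=f"{p.id}|{sp}",
                description="",
            )
            for p in cohort.pairs
        ]
        path = out / f"sequences_{sp}.fasta"
        SeqIO.write(recs, str(path), "fasta")
        written.append(path)

        ivs = [
            p.interval_mel if sp == "mel" else p.interval_vir
            for p in cohort.pairs
        ]
        path = out / f"enhancers_{sp}.bed"
        write_bed(ivs, path)
        written.append(path)

        acc_raw = cohort.acc_raw_mel if sp == "mel" else cohort.acc_raw_vir
        for col in acc_raw.columns:
            tp = col.split(":")[1]
            values = acc_raw.column(col)
            segs = {
                "chrSim": (
                    np.array([iv.start for iv in ivs]),
                    np.array([iv.end for iv in ivs]),
                    values,
                )
            } if ivs else {}
            path = out / f"accessibility_{sp}_{tp}.bedGraph"
            write_bedgraph(SignalTrack(segs), path, name=f"acc_{sp}_{tp}")
            written.append(path)

    for name, table in (
        ("chip_mel", cohort.chip_mel),
        ("chip_vir", cohort.chip_vir),
        ("acc_mel", cohort.acc_mel),
        ("acc_vir", cohort.acc_vir),
        ("acc_raw_mel", cohort.acc_raw_mel),
        ("acc_raw_vir", cohort.acc_raw_vir),
    ):
        path = out / f"{name}.tsv"
        write_score_tsv(table, path)
        written.append(path)

    path = out / "labels.tsv"
    with open(path, "w") as fh:
        fh.write("enhancer\tactivity\n")
        for eid, cls in cohort.labels.items():
            fh.write(f"{eid}\t{cls}\n")
    written.append(path)

    path = out / "pwms.txt"
    write_pwm_file(cohort.config.per_tf_pwm, path)
    written.append(path)

    if cohort.truth is not None:
        path = out / "true_dchip.tsv"
        write_score_tsv(cohort.truth.true_dchip, path)
        written.append(path)

    return written


def read_cohort(indir) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort` (truth optional)."""
    from Bio import SeqIO

    ind = Path(indir)
    seqs: dict[str, dict[str, str]] = {"mel": {}, "vir": {}}
    intervals: dict[str, dict[str, GenomicInterval]] = {"mel": {}, "vir": {}}
    for sp in ("mel", "vir"):
        for rec in SeqIO.parse(str(ind / f"sequences_{sp}.fasta"), "fasta"):
            eid = rec.id.split("|")[0]
            seqs[sp][eid] = str(rec.seq)
        for iv in read_bed(ind / f"enhancers_{sp}.bed"):
            intervals[sp][iv.id] = GenomicInterval(
                iv.chrom, iv.start, iv.end, iv.id, sp
            )

    chip_mel = read_score_tsv(ind / "chip_mel.tsv", "mel", normalized=True)
    chip_vir = read_score_tsv(ind / "chip_vir.tsv", "vir", normalized=True)
    acc_mel = read_score_tsv(ind / "acc_mel.tsv", "mel", normalized=True)
    acc_vir = read_score_tsv(ind / "acc_vir.tsv", "vir", normalized=True)
    acc_raw_mel = read_score_tsv(ind / "acc_raw_mel.tsv", "mel")
    acc_raw_vir = read_score_tsv(ind / "acc_raw_vir.tsv", "vir")

    labels: dict[str, str] = {}
    with open(ind / "labels.tsv") as fh:
        next(fh)
        for line in fh:
            if line.strip():
                eid, cls = line.rstrip("\n").split("\t")
                labels[eid] = cls

    pwms = read_pwm_file(ind / "pwms.txt")
    ids = chip_mel.ids
    pairs = [
        EnhancerPair(
            id=eid,
            interval_mel=intervals["mel"][eid],
            interval_vir=intervals["vir"][eid],
            seq_mel=seqs["mel"][eid],
            seq_vir=seqs["vir"][eid],
        )
        for eid in ids
    ]
    cfg = SimulationConfig(
        n_pairs=len(ids),
        seq_length=len(pairs[0].seq_mel) if pairs else 0,
        per_tf_pwm=pwms,
        conditions=tuple(chip_mel.columns),
    )
    return SyntheticCohort(
        config=cfg,
        pairs=pairs,
        chip_mel=chip_mel,
        chip_vir=chip_vir,
        acc_mel=acc_mel,
        acc_vir=acc_vir,
        acc_raw_mel=acc_raw_mel,
        acc_raw_vir=acc_raw_vir,
        labels=labels,
        truth=None,
    )
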