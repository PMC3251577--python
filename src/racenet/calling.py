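"""Segmentation of per-experiment tiling-array intensities into RACEfrags.

The caller has four parameters: an intensity percentile threshold ``I``
above which a probe is positive, a maximum gap ``M`` in nucleotides between
consecutive positive probes of the same fragment, a minimum run length
``m`` in probes, and a boundary convention ``c`` (middle-to-middle or
start-to-end).  Parameters are optimized by grid search against the median
exonic accuracy of called fragments over projected internal exons, with
splice-site PWM scores at fragment boundaries as a secondary, reference-free
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product as _iterproduct
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ExperimentKey, GenomicInterval, meld_intervals

__all__ = [
    "CallerParams",
    "RACEfrag",
    "SpliceScoreConfig",
    "NEGATIVE_CONTROL_PARAMS",
    "call_racefrags",
    "exonic_accuracy",
    "splice_site_scores",
    "optimize_caller_params",
    "load_default_splice_config",
]


@dataclass(frozen=True)
class CallerParams:
    """RACEfrag caller parameters.

    I: percentile intensity threshold (0 < I < 100); M: max nt gap between
    consecutive positive probes; m: min positive probes per fragment;
    c: boundary convention, "middle" or "startend".
    """

    I: float = 99.1
    M: int = 59
    m: int = 5
    c: str = "middle"

    def __post_init__(self) -> None:
        if not 0 < self.I < 100:
            raise ValueError(f"I must be in (0,100), got {self.I}")
        if self.M < 0 or self.m < 1:
            raise ValueError("require M >= 0 and m >= 1")
        if self.c not in ("middle", "startend"):
            raise ValueError(f"c must be 'middle' or 'startend', got {self.c!r}")


#: The sensitive setting used for negative-control hybridizations.
NEGATIVE_CONTROL_PARAMS = CallerParams(I=99.0, M=25, m=3, c="middle")


@dataclass(frozen=True)
class RACEfrag:
    """A contiguous site of transcription called from one hybridization."""

    interval: GenomicInterval
    experiment: ExperimentKey
    n_probes: int
    mean_intensity: float


def _run_boundaries(probes: pd.DataFrame, c: str) -> GenomicInterval:
    first, last = probes.iloc[0], probes.iloc[-1]
    chrom = first["chrom"]
    if c == "startend":
        return GenomicInterval(chrom, int(first["start"]), int(last["end"]))
    left = (int(first["start"]) + int(first["end"])) // 2
    right = (int(last["start"]) + int(last["end"]) + 1) // 2
    return GenomicInterval(chrom, left, max(left + 1, right))


def call_racefrags(
    track: pd.DataFrame,
    params: CallerParams,
    specific_probes: np.ndarray | None = None,
    experiment: ExperimentKey | None = None,
) -> list[RACEfrag]:
    """Call RACEfrags from one experiment's probe intensity track.

    ``track`` columns: probe_id, chrom, start, end, intensity (and
    optionally pool_id/sample_id, used for the experiment key when
    ``experiment`` is not given).  ``specific_probes`` is a boolean mask
    aligned with ``track`` rows; multi-mapping probes should be masked out
    before calling.  The percentile threshold is computed per experiment
    over specific probes only, and a probe is positive iff its intensity is
    strictly above the threshold, so an all-equal track yields no calls.
    """
    if experiment is None:
        if "pool_id" in track.columns and "sample_id" in track.columns and len(track):
            experiment = ExperimentKey(str(track["pool_id"].iloc[0]), str(track["sample_id"].iloc[0]))
        else:
            experiment = ExperimentKey("pool?", "sample?")
    t = track if specific_probes is None else track.loc[np.asarray(specific_probes, bool)]
    if t.empty:
        return []
    threshold = float(np.percentile(t["intensity"].to_numpy(float), params.I))
    pos = t.loc[t["intensity"].to_numpy(float) > threshold]
    frags: list[RACEfrag] = []
    for _chrom, grp in pos.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(int)
        ends = grp["end"].to_numpy(int)
        # split where the nt gap end-of-probe -> start-of-next exceeds M
        breaks = np.nonzero(starts[1:] - ends[:-1] > params.M)[0] + 1
        for chunk in np.split(np.arange(len(grp)), breaks):
            if len(chunk) < params.m:
                continue
            run = grp.iloc[chunk]
            frags.append(
                RACEfrag(
                    interval=_run_boundaries(run, params.c),
                    experiment=experiment,
                    n_probes=len(run),
                    mean_intensity=float(run["intensity"].mean()),
                )
            )
    return frags


def exonic_accuracy(
    frags: Sequence[RACEfrag | GenomicInterval],
    internal_exons: Sequence[GenomicInterval],
) -> float | None:
    """Median intersection-over-union of internal projected exons vs frags.

    For each internal projected exon overlapped by at least one fragment,
    the accuracy is |exon ∩ frag-union| / |exon ∪ frag-union| in
    nucleotides, with the union taken over the fragments overlapping that
    exon.  Returns the median over covered exons, or ``None`` when no exon
    is covered (distinct from an accuracy of 0).
    """
    ivs = [getattr(f, "interval", f) for f in frags]
    scores = []
    for exon in internal_exons:
        over = meld_intervals(iv for iv in ivs if iv.overlaps(exon))
        if not over:
            continue
        inter = sum(iv.overlap_bp(exon) for iv in over)
        union = len(exon) + sum(len(iv) for iv in over) - inter
        scores.append(inter / union)
    if not scores:
        return None
    return float(np.median(scores))


# ---------------------------------------------------------------------------
# Splice-site scoring


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _load_pwm(name: str, pseudocount: float = 1e-3) -> np.ndarray:
    """Load a frequency matrix data file and convert to log-odds vs a
    uniform background."""
    with resources.files("racenet.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    freq = df[["A", "C", "G", "T"]].to_numpy(float)
    freq = freq / freq.sum(axis=1, keepdims=True)
    return np.log2((freq + pseudocount) / (0.25 + pseudocount))


@dataclass(frozen=True)
class SpliceScoreConfig:
    """Donor/acceptor log-odds PWMs and the half-width of the two windows
    scanned around the left (W1) and right (W2) fragment boundaries."""

    donor_pwm: np.ndarray
    acceptor_pwm: np.ndarray
    window_half: int = 30
    both_strands: bool = False


def load_default_splice_config(window_half: int = 30, both_strands: bool = False) -> SpliceScoreConfig:
    return SpliceScoreConfig(
        donor_pwm=_load_pwm("donor_pwm.tsv"),
        acceptor_pwm=_load_pwm("acceptor_pwm.tsv"),
        window_half=window_half,
        both_strands=both_strands,
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _scan_pwm(seq: str, pwm: np.ndarray) -> float:
    w = pwm.shape[0]
    if len(seq) < w:
        return -np.inf
    best = -np.inf
    for i in range(len(seq) - w + 1):
        s = 0.0
        ok = True
        for j, base in enumerate(seq[i : i + w]):
            k = _BASE_IDX.get(base)
            if k is None:
                ok = False
                break
            s += pwm[j, k]
        if ok and s > best:
            best = s
    return best


def splice_site_scores(
    frag: RACEfrag | GenomicInterval,
    genome: dict[str, str],
    cfg: SpliceScoreConfig,
) -> tuple[float, float]:
    """Best (donor, acceptor) PWM log-odds over the two boundary windows.

    Windows of ``2 * window_half`` nt are centered on the fragment's left
    and right boundaries (clipped at chromosome edges); each is scanned
    with both PWMs and the per-site maxima over the two windows are
    returned.  By default only the + strand of the supplied sequence is
    scored (RACE products are strand-ambiguous on the array); set
    ``both_strands`` to also scan the reverse complement.
    """
    iv = getattr(frag, "interval", frag)
    seq = genome[iv.chrom]
    windows = []
    for anchor in (iv.start, iv.end):
        lo = max(0, anchor - cfg.window_half)
        hi = min(len(seq), anchor + cfg.window_half)
        windows.append(seq[lo:hi].upper())
    donor = acceptor = -np.inf
    for w in windows:
        variants = [w]
        if cfg.both_strands:
            variants.append(w.translate(_COMPLEMENT)[::-1])
        for v in variants:
            donor = max(donor, _scan_pwm(v, cfg.donor_pwm))
            acceptor = max(acceptor, _scan_pwm(v, cfg.acceptor_pwm))
    return donor, acceptor


# ---------------------------------------------------------------------------
# Parameter optimization


def make_grid(
    I_values: Iterable[float],
    M_values: Iterable[int],
    m_values: Iterable[int],
    c_values: Iterable[str] = ("middle",),
) -> list[CallerParams]:
    return [
        CallerParams(I=i, M=M, m=m, c=c)
        for i, M, m, c in _iterproduct(I_values, M_values, m_values, c_values)
    ]


def optimize_caller_params(
    tracks: Sequence[pd.DataFrame],
    internal_exons: Sequence[GenomicInterval],
    grid: Sequence[CallerParams],
    specific_probes: Sequence[np.ndarray] | None = None,
    genome: dict[str, str] | None = None,
    splice_cfg: SpliceScoreConfig | None = None,
) -> tuple[CallerParams, pd.DataFrame]:
    """Exhaustive grid evaluation of the caller against projected internal
    exons.

    The primary metric is the mean over tracks of the median exonic
    accuracy; splice-site scores (mean best donor/acceptor over called
    fragments) are reported as secondary diagnostics when a genome is
    supplied.  The argmax is deterministic with first-in-grid tie-breaking.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if not tracks:
        raise ValueError("need at least one track")
    masks = specific_probes if specific_probes is not None else [None] * len(tracks)
    rows = []
    best_params, best_score = None, -np.inf
    for params in grid:
        accs, donors, acceptors, n_frags = [], [], [], 0
        for track, mask in zip(tracks, masks):
            frags = call_racefrags(track, params, specific_probes=mask)
            n_frags += len(frags)
            acc = exonic_accuracy(frags, internal_exons)
            if acc is not None:
                accs.append(acc)
            if genome is not None and splice_cfg is not None:
                for f in frags:
                    d, a = splice_site_scores(f, genome, splice_cfg)
                    donors.append(d)
                    acceptors.append(a)
        score = float(np.mean(accs)) if accs else np.nan
        rows.append(
            {
                "I": params.I, "M": params.M, "m": params.m, "c": params.c,
                "median_exonic_accuracy": score,
                "n_frags": n_frags,
                "mean_donor_score": float(np.mean(donors)) if donors else np.nan,
                "mean_acceptor_score": float(np.mean(acceptors)) if acceptors else np.nan,
            }
        )
        if not np.isnan(score) and score > best_score:
            best_score, best_params = score, params
    if best_params is None:
        best_params = grid[0]
    return best_params, pd.DataFrame(rows)
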