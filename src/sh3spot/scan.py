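"""PWM scanning of protein sequences with an empirical-null, FDR-based filter.

Every 15-residue window of each protein is scored against a PWM by summing,
per position, the PAM250 substitution scores of the observed residue to
each residue of the PWM column weighted by its frequency:

    score(w) = sum_pos sum_a freq[pos][a] * PAM250[w[pos], a]

Scores are calibrated against a null of randomly sampled 15-mers drawn
from a background residue composition (by default the composition of the
scanned sequences).  With only ~1000 null samples the smallest empirical
p-value is ~1e-3, so the default p-value uses the upper tail of a Gaussian
fitted to the null scores; the purely empirical add-one p-value is kept as
a diagnostic mode.  P-values from all windows of a scan are jointly
converted to q-values by the Benjamini-Hochberg step-up rule and windows
with q below the cutoff (default 1e-4) are reported as hits, annotated
with their motif class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.stats import norm

from .alphabet import AA20, encode
from .motifs import PWM, PWM_WIDTH, find_motif

__all__ = [
    "load_substitution_matrix",
    "score_window",
    "scan_scores",
    "NullModel",
    "sample_null",
    "window_pvalue",
    "bh_correct",
    "ScanHit",
    "HitRun",
    "scan_sequences",
    "merge_hits",
    "residue_composition",
    "write_hits_tsv",
    "write_hits_bed",
]


def load_substitution_matrix(name: str = "PAM250") -> np.ndarray:
    """A 20x20 substitution matrix as ndarray in :data:`AA20` residue order."""
    mat = substitution_matrices.load(name)
    idx = [mat.alphabet.index(a) for a in AA20]
    arr = np.asarray(mat)[np.ix_(idx, idx)]
    return arr.astype(float)


_PAM250 = None


def _default_submat() -> np.ndarray:
    global _PAM250
    if _PAM250 is None:
        _PAM250 = load_substitution_matrix("PAM250")
    return _PAM250


def _contrib_table(pwm: PWM, submat: np.ndarray) -> np.ndarray:
    """(15, 21) lookup: contrib[pos, b] for residue b; sentinel col 20 = 0.

    contrib[pos, b] = sum_a freq[pos, a] * submat[b, a]; unknown residues
    (index 20) contribute nothing to a window's score.
    """
    contrib = pwm.freq @ submat.T  # (15,20)
    return np.hstack([contrib, np.zeros((PWM_WIDTH, 1))])


def score_window(window: str, pwm: PWM, submat: np.ndarray | None = None) -> float:
    """PWM-weighted substitution score of one 15-residue window."""
    if len(window) != PWM_WIDTH:
        raise ValueError(f"window length {len(window)} != PWM width {PWM_WIDTH}")
    submat = _default_submat() if submat is None else submat
    codes = encode(window.upper())
    if (codes == 20).any():
        warnings.warn(
            f"ambiguous residues in window {window!r} scored as 0", stacklevel=2
        )
    contrib = _contrib_table(pwm, submat)
    return float(contrib[np.arange(PWM_WIDTH), codes].sum())


def scan_scores(seq: str, pwm: PWM, submat: np.ndarray | None = None) -> np.ndarray:
    """Scores of every 15-residue window (stride 1) of ``seq``."""
    submat = _default_submat() if submat is None else submat
    codes = encode(seq.upper())
    if len(codes) < PWM_WIDTH:
        return np.empty(0)
    contrib = _contrib_table(pwm, submat)
    windows = np.lib.stride_tricks.sliding_window_view(codes, PWM_WIDTH)
    return contrib[np.arange(PWM_WIDTH)[None, :], windows].sum(axis=1)


def residue_composition(seqs) -> np.ndarray:
    """Empirical residue frequencies (length 20, AA20 order) of sequences."""
    counts = np.zeros(20)
    for s in seqs:
        codes = encode(str(s).upper())
        counts += np.bincount(codes[codes < 20], minlength=20)
    total = counts.sum()
    if total == 0:
        raise ValueError("no standard residues in sequences")
    return counts / total


@dataclass
class NullModel:
    """Null score distribution of a PWM against a background composition."""

    pwm_id: str
    null_scores: np.ndarray
    background: np.ndarray
    seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.null_scores = np.asarray(self.null_scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if len(self.null_scores) < 100:
            raise ValueError("null model needs at least 100 sampled scores")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        self.mean = float(self.null_scores.mean())
        self.sd = float(self.null_scores.std(ddof=1))
        if self.sd <= 1e-12 * max(1.0, abs(self.mean)):
            raise ValueError("degenerate null: zero score variance")

    @property
    def n(self) -> int:
        return len(self.null_scores)


def sample_null(
    pwm: PWM,
    background: np.ndarray,
    n: int = 1000,
    seed: int = 0,
    submat: np.ndarray | None = None,
) -> NullModel:
    """Score ``n`` random 15-mers drawn positionwise from ``background``.

    The Gaussian (mean, sd) is fitted by moments; sampling is fully
    deterministic under ``seed``.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    background = np.asarray(background, dtype=float)
    submat = _default_submat() if submat is None else submat
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n, PWM_WIDTH), p=background / background.sum())
    contrib = _contrib_table(pwm, submat)
    scores = contrib[np.arange(PWM_WIDTH)[None, :], draws].sum(axis=1)
    return NullModel(pwm.source_domain or "pwm", scores, background, seed)


def window_pvalue(score, null: NullModel, mode: str = "gaussian"):
    """Upper-tail probability of a score under the null model.

    ``gaussian``: tail of the moment-fitted Normal; ``empirical``:
    add-one rule ``(1 + #{null >= score}) / (1 + n)``.  Accepts scalars or
    arrays.
    """
    score = np.asarray(score, dtype=float)
    if mode == "gaussian":
        p = norm.sf(score, loc=null.mean, scale=null.sd)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    elif mode == "empirical":
        ge = (null.null_scores[None, :] >= score.reshape(-1, 1)).sum(axis=1)
        p = (1.0 + ge) / (1.0 + null.n)
        p = p.reshape(score.shape)
    else:
        raise ValueError("mode must be 'gaussian' or 'empirical'")
    return float(p) if p.ndim == 0 else p


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j>=i} p_(j) * m / j`` on the sorted p-values, capped at
    1; monotone (raising any p never lowers any q) and permutation
    equivariant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-d vector")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class ScanHit:
    """One significant 15-residue window."""

    protein_id: str
    start: int  # 0-based; window is protein[start:start+15]
    window: str
    score: float
    p: float
    q: float
    motif_class: str

    @property
    def end(self) -> int:
        return self.start + PWM_WIDTH


@dataclass(frozen=True)
class HitRun:
    """A maximal run of overlapping significant windows on one protein."""

    protein_id: str
    start: int
    end: int
    n_windows: int
    best: ScanHit


def _as_protein_dict(proteins) -> dict[str, str]:
    if isinstance(proteins, (str, bytes)) or hasattr(proteins, "__fspath__"):
        return {r.id: str(r.seq) for r in SeqIO.parse(proteins, "fasta")}
    if isinstance(proteins, dict):
        return {str(k): str(v) for k, v in proteins.items()}
    return {r.id: str(r.seq) for r in proteins}


def scan_sequences(
    proteins,
    pwm: PWM,
    null: NullModel | None = None,
    q_max: float = 1e-4,
    p_mode: str = "gaussian",
    *,
    null_n: int = 1000,
    seed: int = 0,
    submat: np.ndarray | None = None,
) -> list[ScanHit]:
    """Scan proteins with a PWM and keep windows significant at q < q_max.

    ``proteins`` may be a FASTA path, a dict id -> sequence, or an iterable
    of SeqRecords.  BH correction is applied jointly across *all* windows
    of the scanned set.  If no ``null`` model is supplied one is sampled
    from the scanned set's residue composition (``null_n`` 15-mers,
    deterministic under ``seed``).  Proteins shorter than 15 residues are
    skipped with a warning.
    """
    prot = _as_protein_dict(proteins)
    submat = _default_submat() if submat is None else submat
    if null is None:
        bg = residue_composition(prot.values())
        null = sample_null(pwm, bg, n=null_n, seed=seed, submat=submat)

    ids, starts, scores = [], [], []
    for pid, seq in prot.items():
        if len(seq) < PWM_WIDTH:
            warnings.warn(f"protein {pid} shorter than {PWM_WIDTH}; skipped",
                          stacklevel=2)
            continue
        s = scan_scores(seq, pwm, submat)
        ids.extend([pid] * len(s))
        starts.extend(range(len(s)))
        scores.append(s)
    if not scores:
        return []
    scores = np.concatenate(scores)
    p = window_pvalue(scores, null, mode=p_mode)
    q = bh_correct(p)

    hits = []
    for i in np.flatnonzero(q < q_max):
        pid, start = ids[i], starts[i]
        window = prot[pid][start : start + PWM_WIDTH]
        cls = find_motif(window, allow_ambiguous=True).name
        hits.append(ScanHit(pid, start, window, float(scores[i]),
                            float(p[i]), float(q[i]), cls))
    hits.sort(key=lambda h: (h.protein_id, h.start))
    return hits


def merge_hits(hits: list[ScanHit]) -> list[HitRun]:
    """Merge overlapping significant windows into runs per protein.

    Consecutive windows overlapping by at least one residue join a run;
    the run's representative is its maximum-score window.
    """
    runs: list[HitRun] = []
    cur: list[ScanHit] = []
    for h in sorted(hits, key=lambda h: (h.protein_id, h.start)):
        if cur and h.protein_id == cur[-1].protein_id and h.start < cur[-1].end:
            cur.append(h)
        else:
            if cur:
                runs.append(_close_run(cur))
            cur = [h]
    if cur:
        runs.append(_close_run(cur))
    return runs


def _close_run(windows: list[ScanHit]) -> HitRun:
    best = max(windows, key=lambda h: h.score)
    return HitRun(
        windows[0].protein_id,
        windows[0].start,
        windows[-1].end,
        len(windows),
        best,
    )


def write_hits_tsv(hits: list[ScanHit], path, header_lines=None) -> None:
    """Hit table; coordinates are 1-based inclusive in this report."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("protein_id\tstart\tend\twindow\tscore\tp\tq\tmotif_class\n")
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.start + 1}\t{h.end}\t{h.window}\t"
                f"{h.score:.4f}\t{h.p:.4g}\t{h.q:.4g}\t{h.motif_class}\n"
            )


def write_hits_bed(hits: list[ScanHit], path) -> None:
    """BED6+2: chrom start end name score strand p q (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.protein_id}\t{h.start}\t{h.end}\t{h.motif_class}\t"
                f"{h.score:.4f}\t.\t{h.p:.4g}\t{h.q:.4g}\n"
            )
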