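"""SH3 ligand motif classes, top-peptide selection, alignment, PWMs and logos.

SH3 domains bind proline-rich peptides.  The canonical ligand classes are

* **Type I** — ``+xxPxxP`` (``+`` is Arg or Lys),
* **Type II** — ``PxxPx+``,
* **Type I*** — a Type I-like motif in which a hydrophobic residue replaces
  the first proline (``+xxΦxxP``, Φ ∈ {A,V,L,I,M,F,W,Y}),
* **Type III** — a polyproline stretch devoid of charged residues.

This module classifies 15-mer peptides into these classes, selects the
top-binding peptides of a domain profile, anchor-aligns them, and turns the
aligned block into a 15-column position-weight matrix (PWM) of residue
frequencies, plus an information-content logo export.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, AA_INDEX, validate_sequence

PWM_WIDTH = 15

#: Class precedence when several templates match one peptide.
CLASS_PRECEDENCE = ("II", "I", "I*", "III")

CLASSES = ("I", "II", "I*", "III")

HYDROPHOBIC = "AVLIMFWY"

# Overlapping matches via lookahead; group 1 carries the span.
_RE = {
    "I": re.compile(r"(?=([RK]..P..P))"),
    "II": re.compile(r"(?=(P..P.[RK]))"),
    "I*": re.compile(rf"(?=([RK]..[{HYDROPHOBIC}]..P))"),
    "III": re.compile(r"(?=(P..P..P))"),
}

SPAN_LEN = {"I": 7, "II": 6, "I*": 7, "III": 7}


@dataclass(frozen=True)
class MotifMatch:
    """A classified motif occurrence: class name plus matched span."""

    name: str  # one of CLASSES or "none"
    start: int = -1
    end: int = -1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _find_class(seq: str, cls: str) -> MotifMatch | None:
    """Leftmost occurrence of a single class template, or None."""
    if cls in ("I", "II", "I*"):
        m = _RE[cls].search(seq)
        if m:
            return MotifMatch(cls, m.start(1), m.start(1) + SPAN_LEN[cls])
        return None
    # Type III: PxxPxxP span free of R/K, or >=4 P in any 8-residue window
    # free of R/K.  Leftmost qualifying span wins.
    best: tuple[int, int] | None = None
    for m in _RE["III"].finditer(seq):
        s = m.start(1)
        span = seq[s : s + 7]
        if "R" not in span and "K" not in span:
            best = (s, s + 7)
            break
    for s in range(0, len(seq) - 7):
        win = seq[s : s + 8]
        if win.count("P") >= 4 and "R" not in win and "K" not in win:
            if best is None or s < best[0]:
                best = (s, s + 8)
            break
    if best is None:
        return None
    return MotifMatch("III", *best)


def find_motif(seq: str, *, allow_ambiguous: bool = False) -> MotifMatch:
    """Classify a peptide/window, returning the match with coordinates.

    Precedence is II > I > I* > III; within a class the leftmost
    occurrence is reported.  Sequences matching no template return a
    ``MotifMatch("none")``.
    """
    s = validate_sequence(seq, allow_ambiguous=allow_ambiguous)
    if len(s) < 7:
        raise ValueError("motif classification needs at least 7 residues")
    for cls in CLASS_PRECEDENCE:
        hit = _find_class(s, cls)
        if hit is not None:
            return hit
    return MotifMatch("none")


def classify_motif(seq: str) -> str:
    """Class name of the dominant ligand motif in ``seq`` ('none' if absent)."""
    return find_motif(seq).name


# ---------------------------------------------------------------------------
# top-peptide selection


def select_top_peptides(
    profile: pd.Series,
    *,
    top_n: int | None = None,
    percentile: float | None = None,
) -> pd.Series:
    """Rank a binding profile and keep its strongest peptides.

    Exactly one of ``top_n`` and ``percentile`` must be given.  ``top_n``
    returns the n highest-intensity probes (ties broken by probe id);
    ``percentile=p`` returns the probes with intensity strictly above the
    p-th percentile of the profile (so ``percentile=95`` keeps roughly the
    top 5%).
    """
    if profile.empty:
        raise ValueError("empty binding profile")
    if (top_n is None) == (percentile is None):
        raise ValueError("give exactly one of top_n or percentile")
    order = profile.iloc[np.lexsort((profile.index.astype(str), -profile.values))]
    if top_n is not None:
        if top_n > len(profile):
            raise ValueError(f"top_n={top_n} exceeds library size {len(profile)}")
        return order.iloc[:top_n]
    cut = np.percentile(profile.values, percentile)
    return order[order > cut]


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class AlignedRow:
    probe_id: str
    sequence: str
    motif_class: str
    offset: int
    row: str  # 15 columns, '-' for gap
    secondary: bool  # True when the peptide's class differs from the anchor


@dataclass
class AlignedPeptideBlock:
    rows: list[AlignedRow]
    anchor_class: str
    anchor_column: int

    def __len__(self) -> int:
        return len(self.rows)

    def extract(self) -> list[tuple[str, str]]:
        """Recover (probe_id, ungapped sequence) pairs from the rows."""
        return [(r.probe_id, r.row.replace("-", "")) for r in self.rows]


def _anchor_position(seq: str, match: MotifMatch) -> int:
    """Column on which a classified peptide is anchored for alignment.

    Types I and I* anchor on the charged residue, Type II on the first
    core proline; Type III anchors on the first proline of the longest
    proline run (ties leftmost).
    """
    if match.name in ("I", "I*", "II"):
        return match.start
    best_start, best_len = 0, 0
    for m in re.finditer(r"P+", seq):
        if m.end() - m.start() > best_len:
            best_start, best_len = m.start(), m.end() - m.start()
    return best_start


def align_peptides(
    peptides: Iterable[tuple[str, str]] | pd.Series,
    class_hint: str = "auto",
) -> AlignedPeptideBlock:
    """Anchor-align peptides of a (majority) motif class into 15 columns.

    Peptides of the anchor class are shifted so their anchor residue sits in
    one shared column (the most common anchor position; ties resolved to the
    larger position, which keeps motif spans inside the 15 columns);
    overhangs are trimmed and short ends gap-padded.  Peptides of other
    classes (or with no motif) are stacked unshifted and flagged secondary.
    """
    if isinstance(peptides, pd.Series):
        items = [(str(k), str(v)) for k, v in peptides.items()]
    else:
        items = [(str(k), validate_sequence(v)) for k, v in peptides]
    if len(items) < 2:
        raise ValueError("alignment needs at least 2 peptides")

    matches = {pid: find_motif(seq) for pid, seq in items}
    classified = [m.name for m in matches.values() if m.name != "none"]
    if class_hint == "auto":
        if not classified:
            raise ValueError(
                "no peptide matches any motif class; pass class_hint='none' "
                "to force offset-0 stacking"
            )
        counts = Counter(classified)
        top = max(counts.values())
        anchor_class = next(c for c in CLASS_PRECEDENCE if counts.get(c, 0) == top)
    else:
        anchor_class = class_hint

    anchors = {
        pid: _anchor_position(seq, matches[pid])
        for pid, seq in items
        if matches[pid].name == anchor_class
    }
    if anchors:
        cnt = Counter(anchors.values())
        top = max(cnt.values())
        target = max(p for p, c in cnt.items() if c == top)
    else:
        target = 0

    rows = []
    for pid, seq in items:
        m = matches[pid]
        secondary = m.name != anchor_class
        offset = 0 if secondary else target - anchors[pid]
        row = "".join(
            seq[c - offset] if 0 <= c - offset < len(seq) else "-"
            for c in range(PWM_WIDTH)
        )
        rows.append(AlignedRow(pid, seq, m.name, offset, row, secondary))
    return AlignedPeptideBlock(rows, anchor_class, target)


# ---------------------------------------------------------------------------
# PWMs


@dataclass
class PWM:
    """15-column amino-acid frequency matrix built from aligned peptides.

    ``freq`` has shape (15, 20) with residue columns ordered as
    :data:`~sh3spot.alphabet.AA20`; every position row sums to 1.
    """

    freq: np.ndarray
    source_domain: str = ""
    n_peptides: int = 0

    width: int = field(default=PWM_WIDTH, init=False)

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (PWM_WIDTH, 20):
            raise ValueError(f"PWM must be {PWM_WIDTH}x20, got {self.freq.shape}")
        if np.any(self.freq < 0):
            raise ValueError("PWM frequencies must be non-negative")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM position must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq.T, index=list(AA20), columns=range(1, PWM_WIDTH + 1)
        )


def build_pwm(
    block: AlignedPeptideBlock,
    pseudocount: float = 0.0,
    *,
    source_domain: str = "",
    include_secondary: bool = True,
) -> PWM:
    """Column-wise residue frequencies of an aligned block.

    ``freq[pos][a] = (count(a at pos) + pseudocount) /
    (non-gap rows at pos + 20 * pseudocount)``; gap cells contribute
    nothing to either numerator or denominator.
    """
    rows = [r for r in block.rows if include_secondary or not r.secondary]
    if not rows:
        raise ValueError("empty aligned block")
    counts = np.zeros((PWM_WIDTH, 20))
    for r in rows:
        for pos, ch in enumerate(r.row):
            if ch != "-":
                counts[pos, AA_INDEX[ch]] += 1
    nongap = counts.sum(axis=1)
    if pseudocount == 0 and np.any(nongap == 0):
        raise ValueError("column with zero non-gap rows needs pseudocount > 0")
    freq = (counts + pseudocount) / (nongap + 20 * pseudocount)[:, None]
    return PWM(freq, source_domain=source_domain, n_peptides=len(rows))


def pwm_from_peptides(
    peptides: pd.Series | Sequence[tuple[str, str]],
    pseudocount: float = 0.01,
    *,
    source_domain: str = "",
    class_hint: str = "auto",
) -> PWM:
    """Convenience: align peptides and build a scanning PWM in one step."""
    block = align_peptides(peptides, class_hint=class_hint)
    return build_pwm(block, pseudocount, source_domain=source_domain)


def export_logo(pwm: PWM) -> pd.DataFrame:
    """Per-column letter heights of an information-content sequence logo.

    A column's information content is ``IC = log2(20) + sum_a f log2 f``
    (with ``0 log 0 = 0``); each residue's letter height is ``f * IC``.
    Returns a (15, 20) DataFrame of heights with an ``IC`` attribute column
    appended as ``heights.attrs['ic']``.
    """
    f = pwm.freq
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    ic = np.log2(20) + plogp.sum(axis=1)
    heights = pd.DataFrame(
        f * ic[:, None], index=range(1, PWM_WIDTH + 1), columns=list(AA20)
    )
    heights.attrs["ic"] = ic
    return heights


def sample_from_pwm(pwm: PWM, n: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` 15-mers position-independently from the PWM columns."""
    out = []
    cum = pwm.freq.cumsum(axis=1)
    for _ in range(n):
        u = rng.random(PWM_WIDTH)
        idx = (u[:, None] > cum).sum(axis=1)
        out.append("".join(AA20[i] for i in idx))
    return out


def consensus_pwm(
    motif_class: str,
    strength: float = 0.95,
    *,
    source_domain: str = "",
) -> PWM:
    """An idealized, high-information PWM for one ligand class.

    Template positions (the motif span, placed at offset 4 of the 15
    columns) put probability ``strength`` on the consensus residue and
    spread the remainder uniformly; flanking positions are uniform.  Used
    to plant recognizable sites in synthetic proteomes and as a
    "gain-matched" scanning query in benchmarks.
    """
    templates = {
        "I": {4: "R", 7: "P", 10: "P"},
        "II": {4: "P", 7: "P", 9: "R"},
        "I*": {4: "R", 7: "L", 10: "P"},
        "III": {i: "P" for i in range(4, 12)},
    }
    if motif_class not in templates:
        raise ValueError(f"unknown motif class {motif_class!r}")
    freq = np.full((PWM_WIDTH, 20), 1.0 / 20)
    for pos, res in templates[motif_class].items():
        freq[pos] = (1.0 - strength) / 19
        freq[pos, AA_INDEX[res]] = strength
    return PWM(freq, source_domain=source_domain or f"consensus-{motif_class}")


# ---------------------------------------------------------------------------
# PWM I/O (JASPAR-style plain text and TSV)


def write_pwm(pwm: PWM, path, fmt: str = "jaspar") -> None:
    """Write a PWM as JASPAR-style text (residue rows) or as TSV."""
    if fmt == "tsv":
        pwm.to_frame().to_csv(path, sep="\t", float_format="%.6g")
        return
    with open(path, "w") as fh:
        fh.write(f">{pwm.source_domain or 'pwm'} n_peptides={pwm.n_peptides}\n")
        for i, a in enumerate(AA20):
            vals = " ".join(f"{v:.6f}" for v in pwm.freq[:, i])
            fh.write(f"{a} [ {vals} ]\n")


def read_pwm(path) -> PWM:
    """Read a PWM written by :func:`write_pwm` (JASPAR-style text)."""
    name, n_pep = "", 0
    freq = np.zeros((PWM_WIDTH, 20))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                name = parts[0] if parts else ""
                for p in parts[1:]:
                    if p.startswith("n_peptides="):
                        n_pep = int(p.split("=", 1)[1])
                continue
            a, rest = line.split(None, 1)
            vals = [float(x) for x in rest.strip("[] \t").split()]
            if len(vals) != PWM_WIDTH:
                raise ValueError(f"expected {PWM_WIDTH} columns for residue {a}")
            freq[:, AA_INDEX[a]] = vals
    # renormalize away text round-off
    freq /= freq.sum(axis=1, keepdims=True)
    return PWM(freq, source_domain=name, n_peptides=n_pep)
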