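"""Within-family sequence identity versus binding-profile correlation.

For every pair of SH3 domains in the same family the percent identity of
their domain sequences (global alignment) is compared with the Pearson
correlation of their normalized SPOT binding profiles.  A monotone
association between the two says that sequence conservation predicts
conserved binding specificity; family members that break the trend
(high identity, low profile correlation) are flagged as outliers — the
signature of a specificity switch that plain sequence divergence cannot
explain.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy.stats import rankdata, spearmanr

from .alphabet import validate_sequence
from .normalize import ProfilePanel


@dataclass(frozen=True)
class DomainRecord:
    """One SH3 domain sequence with its family/species metadata."""

    domain_id: str
    species: str
    family: str
    sequence: str
    paralog_flag: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for domain {self.domain_id}")
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))


def read_domains(fasta_path, metadata_tsv) -> list[DomainRecord]:
    """Load domain sequences (FASTA) and their family/species table (TSV).

    The metadata TSV needs columns ``domain_id``, ``family``, ``species``
    and optionally ``paralog``.
    """
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(fasta_path, "fasta")}
    meta = pd.read_csv(metadata_tsv, sep="\t", comment="#", dtype=str)
    records = []
    for _, row in meta.iterrows():
        did = row["domain_id"]
        if did not in seqs:
            raise ValueError(f"domain {did} in metadata but not in FASTA")
        records.append(
            DomainRecord(
                did,
                row["species"],
                row["family"],
                seqs[did],
                str(row.get("paralog", "0")) in ("1", "True", "true"),
            )
        )
    return records


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = None


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions in a global alignment of a and b.

    Needleman-Wunsch with BLOSUM62, gap open 10 / extend 0.5.  The
    denominator counts aligned columns excluding terminal gaps; internal
    gap columns count as mismatches.  Symmetric by construction (the two
    sequences are ordered canonically before aligning).
    """
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    a = validate_sequence(a)
    b = validate_sequence(b)
    if not a or not b:
        raise ValueError("both sequences must be nonempty")
    x, y = sorted((a, b))
    aln = _ALIGNER.align(x, y)[0]
    row_x, row_y = str(aln[0]), str(aln[1])
    # trim terminal gap columns on either row
    lo = 0
    hi = len(row_x)
    while lo < hi and (row_x[lo] == "-" or row_y[lo] == "-"):
        lo += 1
    while hi > lo and (row_x[hi - 1] == "-" or row_y[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    same = sum(1 for i in range(lo, hi) if row_x[i] == row_y[i] and row_x[i] != "-")
    return same / (hi - lo)


def family_pairs(domains: list[DomainRecord], panel: ProfilePanel) -> pd.DataFrame:
    """One record per unordered within-family pair of profiled domains.

    Columns: ``domain_a domain_b family relation identity profile_r``;
    ``relation`` is ``intra-species`` when both domains come from the same
    species.  Pairs lacking a binding profile are skipped with a warning.
    """
    import warnings

    by_family: dict[str, list[DomainRecord]] = {}
    for d in domains:
        by_family.setdefault(d.family, []).append(d)

    rows = []
    for fam in sorted(by_family):
        members = sorted(by_family[fam], key=lambda d: d.domain_id)
        for da, db in combinations(members, 2):
            if da.domain_id not in panel.values.columns or (
                db.domain_id not in panel.values.columns
            ):
                warnings.warn(
                    f"pair ({da.domain_id}, {db.domain_id}) lacks a profile; skipped",
                    stacklevel=2,
                )
                continue
            r = float(
                np.corrcoef(
                    panel.values[da.domain_id], panel.values[db.domain_id]
                )[0, 1]
            )
            rows.append(
                {
                    "domain_a": da.domain_id,
                    "domain_b": db.domain_id,
                    "family": fam,
                    "relation": "intra-species"
                    if da.species == db.species
                    else "inter-species",
                    "identity": pairwise_identity(da.sequence, db.sequence),
                    "profile_r": r,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["domain_a", "domain_b", "family", "relation", "identity", "profile_r"],
    )


@dataclass
class ConservationSummary:
    per_family: pd.DataFrame  # family x (n_pairs, mean_identity, mean_profile_r)
    spearman_rho: float  # global identity-vs-r rank correlation (NaN if undefined)
    p_permutation: float
    n_permutations: int
    family_order: list[str]  # high -> low sequence and specificity conservation


def conservation_summary(
    pairs: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> ConservationSummary:
    """Global and per-family association between identity and profile r.

    The global statistic is the Spearman rank correlation of identity vs
    profile correlation over all within-family pairs, with a seeded
    permutation p-value (profile_r shuffled across pairs).  Families are
    ordered from high to low combined sequence and specificity
    conservation (average of the two mean-rank orderings).
    """
    if len(pairs) < 3:
        raise ValueError("conservation summary needs at least 3 pairs")
    per_family = pairs.groupby("family").agg(
        n_pairs=("identity", "size"),
        mean_identity=("identity", "mean"),
        mean_profile_r=("profile_r", "mean"),
    )

    ident = pairs["identity"].to_numpy()
    prof = pairs["profile_r"].to_numpy()
    if np.ptp(ident) == 0 or np.ptp(prof) == 0:
        rho, p_perm = float("nan"), float("nan")
    else:
        rho = float(spearmanr(ident, prof).statistic)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(prof)
            r = spearmanr(ident, perm).statistic
            if abs(r) >= abs(rho):
                count += 1
        p_perm = (count + 1) / (n_permutations + 1)

    rank_id = rankdata(-per_family["mean_identity"])
    rank_r = rankdata(-per_family["mean_profile_r"])
    order_idx = np.lexsort((per_family.index.astype(str), rank_id + rank_r))
    family_order = [per_family.index[i] for i in order_idx]
    return ConservationSummary(per_family, rho, p_perm, n_permutations, family_order)


def family_outliers(pairs: pd.DataFrame) -> pd.DataFrame:
    """Flag, per family, the pair most out of step with the identity~r trend.

    Within each family, pairs are ranked by identity and by profile
    correlation (average ranks on ties); the outlier is the pair whose
    identity rank most exceeds its correlation rank — a high-identity,
    low-correlation pair, the signature of a specificity switch in an
    otherwise conserved family.
    """
    rows = []
    for fam, grp in pairs.groupby("family"):
        if len(grp) < 2:
            continue
        id_rank = rankdata(grp["identity"])
        r_rank = rankdata(grp["profile_r"])
        gap = id_rank - r_rank
        i = int(np.argmax(gap))
        rows.append(
            {
                "family": fam,
                "domain_a": grp.iloc[i]["domain_a"],
                "domain_b": grp.iloc[i]["domain_b"],
                "rank_gap": float(gap[i]),
                "identity": float(grp.iloc[i]["identity"]),
                "profile_r": float(grp.iloc[i]["profile_r"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "domain_a", "domain_b", "rank_gap", "identity", "profile_r"],
    )
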