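"""Motif classification, top-peptide selection, alignment, PWMs, logos."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sh3spot.alphabet import AA20
from sh3spot import motifs
from sh3spot.motifs import (
    AlignedPeptideBlock,
    align_peptides,
    build_pwm,
    classify_motif,
    consensus_pwm,
    export_logo,
    find_motif,
    read_pwm,
    sample_from_pwm,
    select_top_peptides,
    write_pwm,
)

HYDRO = set("AVLIMFWY")


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("SSSSTPPTLPPRRIE", "II"),  # canonical PxxPx+ ligand
        ("ITHRLRISIPGITGR", "I*"),  # +xxΦxxP with Ile in the proline slot
        ("AAAAAAAAAAAAAAA", "none"),
        ("GRAAPAAPAAAAAAA", "I"),  # +xxPxxP
        ("GPAAPARAAAAAAAA", "II"),
        ("APAAPAAPAAAAAAA", "III"),  # PxxPxxP, no charge
        ("AAPPPPAAAAAAAAA", "III"),  # >=4 P in an 8-residue window
        ("AAPPPPRAAAAAAAA", "none"),  # charge inside the polyproline span
    ],
)
def test_classification_examples(seq, expected):
    assert classify_motif(seq) == expected


def test_classifier_rejects_bad_input():
    with pytest.raises(ValueError):
        classify_motif("APAAPA1PAAAAAAA")
    with pytest.raises(ValueError):
        classify_motif("APP")  # shorter than a motif span


def _oracle_class(seq: str) -> str:
    """Brute-force template enumeration with explicit precedence."""

    def is_I(w):
        return w[0] in "RK" and w[3] == "P" and w[6] == "P"

    def is_II(w):
        return w[0] == "P" and w[3] == "P" and w[5] in "RK"

    def is_Istar(w):
        return w[0] in "RK" and w[3] in HYDRO and w[6] == "P"

    for cls, span, fn in (("II", 6, is_II), ("I", 7, is_I), ("I*", 7, is_Istar)):
        for off in range(len(seq) - span + 1):
            if fn(seq[off : off + span]):
                return cls
    for off in range(len(seq) - 6):
        w = seq[off : off + 7]
        if w[0] == "P" and w[3] == "P" and w[6] == "P" and not set(w) & set("RK"):
            return "III"
    for off in range(len(seq) - 7):
        w = seq[off : off + 8]
        if w.count("P") >= 4 and not set(w) & set("RK"):
            return "III"
    return "none"


def test_classifier_agrees_with_bruteforce_oracle(rng):
    """Regex path and independent window enumeration agree on 10,000 15-mers."""
    # enrich P/R/K so every class occurs often
    probs = np.ones(20)
    for a in "PRK":
        probs[AA20.index(a)] = 4.0
    probs /= probs.sum()
    for _ in range(10_000):
        seq = "".join(AA20[i] for i in rng.choice(20, 15, p=probs))
        assert classify_motif(seq) == _oracle_class(seq), seq


def test_match_coordinates_are_retrievable():
    m = find_motif("SSSSTPPTLPPRRIE")
    assert (m.name, m.start, m.end) == ("II", 6, 12)
    assert "SSSSTPPTLPPRRIE"[m.start] == "P"


# ---------------------------------------------------------------------------
# top-peptide selection


def test_select_top_peptides_modes():
    profile = pd.Series(
        np.arange(1, 293, dtype=float), index=[f"p{i:04d}" for i in range(1, 293)]
    )
    top = select_top_peptides(profile, top_n=10)
    assert list(top.values) == list(range(292, 282, -1))
    above = select_top_peptides(profile, percentile=95)
    assert len(above) == 15  # ceil(0.05 * 292) with no ties
    assert (above.values > np.percentile(profile.values, 95)).all()
    everything = select_top_peptides(profile, top_n=292)
    assert list(everything.values) == list(range(292, 0, -1))


def test_select_top_peptides_tie_break_and_errors():
    profile = pd.Series([1.0, 1.0, 0.5], index=["b", "a", "c"])
    top = select_top_peptides(profile, top_n=2)
    assert list(top.index) == ["a", "b"]  # ties broken by probe id
    with pytest.raises(ValueError):
        select_top_peptides(profile, top_n=4)
    with pytest.raises(ValueError):
        select_top_peptides(profile, top_n=1, percentile=95)
    with pytest.raises(ValueError):
        select_top_peptides(pd.Series(dtype=float), top_n=1)


# ---------------------------------------------------------------------------
# alignment


def test_align_identical_peptides_offset_zero():
    block = align_peptides([("a", "SSSSTPPTLPPRRIE"), ("b", "SSSSTPPTLPPRRIE")])
    assert block.anchor_class == "II"
    assert all(r.offset == 0 for r in block.rows)
    assert block.rows[0].row == block.rows[1].row == "SSSSTPPTLPPRRIE"


def test_align_shifted_core_lands_in_same_column():
    a = "SSSSTPPTLPPRRIE"  # II anchor (first core P) at position 6
    b = "SSTPPTLPPRRIEAA"  # same core shifted left by 2 -> anchor at 4
    block = align_peptides([("a", a), ("b", b)])
    rows = {r.probe_id: r for r in block.rows}
    assert rows["a"].offset - rows["b"].offset == -2
    col = block.anchor_column
    assert rows["a"].row[col] == "P" and rows["b"].row[col] == "P"
    # whole cores coincide
    assert rows["a"].row[col : col + 6] == rows["b"].row[col : col + 6]


def test_align_minority_class_flagged_secondary():
    peptides = [
        ("a", "SSSSTPPTLPPRRIE"),  # II
        ("b", "SSSSTPPTLPPRRIE"),  # II
        ("c", "GRAAPAAPAAAAAAA"),  # I
    ]
    block = align_peptides(peptides)
    assert block.anchor_class == "II"
    flags = {r.probe_id: r.secondary for r in block.rows}
    assert flags == {"a": False, "b": False, "c": True}
    assert next(r for r in block.rows if r.probe_id == "c").offset == 0


def test_align_no_match_raises_unless_forced():
    peptides = [("a", "A" * 15), ("b", "G" * 15)]
    with pytest.raises(ValueError):
        align_peptides(peptides)
    block = align_peptides(peptides, class_hint="none")
    assert all(r.offset == 0 for r in block.rows)


def test_align_is_idempotent_on_reextracted_block():
    peptides = [
        ("a", "SSSSTPPTLPPRRIE"),
        ("b", "SSTPPTLPPRRIEAA"),
        ("c", "TPPTLPPRRIEAAAA"),
    ]
    first = align_peptides(peptides)
    second = align_peptides(first.extract())
    assert [r.offset for r in second.rows] == [r.offset for r in first.rows]
    assert second.anchor_column == first.anchor_column


# ---------------------------------------------------------------------------
# PWMs


def test_build_pwm_indicator_columns():
    block = align_peptides([("a", "SSSSTPPTLPPRRIE"), ("b", "SSSSTPPTLPPRRIE")])
    pwm = build_pwm(block, pseudocount=0.0)
    assert pwm.n_peptides == 2
    for pos, ch in enumerate("SSSSTPPTLPPRRIE"):
        assert pwm.freq[pos, AA20.index(ch)] == 1.0
        assert pwm.freq[pos].sum() == pytest.approx(1.0)


def test_build_pwm_pseudocount_single_row():
    block = align_peptides(
        [("a", "SSSSTPPTLPPRRIE"), ("b", "SSSSTPPTLPPRRIE")]
    )
    block.rows = block.rows[:1]  # one observation per column
    pwm = build_pwm(block, pseudocount=1.0)
    # observed residue: (1+1)/(1+20); others 1/21
    assert pwm.freq[5, AA20.index("P")] == pytest.approx(2 / 21)
    assert pwm.freq[5, AA20.index("W")] == pytest.approx(1 / 21)
    np.testing.assert_allclose(pwm.freq.sum(axis=1), 1.0, atol=1e-9)


def test_build_pwm_gap_columns_need_pseudocount():
    block = align_peptides([("a", "SSTPPTLPPRRIEAA"), ("b", "TPPTLPPRRIEAAAA")])
    assert any("-" in r.row for r in block.rows)
    pwm = build_pwm(block, pseudocount=0.01)
    np.testing.assert_allclose(pwm.freq.sum(axis=1), 1.0, atol=1e-9)
    empty = AlignedPeptideBlock(rows=[], anchor_class="II", anchor_column=0)
    with pytest.raises(ValueError):
        build_pwm(empty)


def test_pwm_sampling_roundtrip_recovers_frequencies(rng):
    """Sampling 10,000 peptides from a PWM and recounting recovers it."""
    pwm = consensus_pwm("II", strength=0.8)
    samples = sample_from_pwm(pwm, 10_000, rng)
    counts = np.zeros((15, 20))
    for s in samples:
        for pos, ch in enumerate(s):
            counts[pos, AA20.index(ch)] += 1
    np.testing.assert_allclose(counts / 10_000, pwm.freq, atol=0.02)


def test_pwm_io_roundtrip(tmp_path):
    pwm = consensus_pwm("I", strength=0.9)
    path = tmp_path / "x.pwm"
    write_pwm(pwm, path)
    back = read_pwm(path)
    np.testing.assert_allclose(back.freq, pwm.freq, atol=1e-5)
    assert back.source_domain == pwm.source_domain
    write_pwm(pwm, tmp_path / "x.tsv", fmt="tsv")
    assert (tmp_path / "x.tsv").read_text().startswith("\t1\t2")


def test_pwm_validation():
    bad = np.full((15, 20), 0.05)
    bad[0, 0] = 0.5
    with pytest.raises(ValueError):
        motifs.PWM(bad)
    with pytest.raises(ValueError):
        motifs.PWM(np.full((10, 20), 0.05))


# ---------------------------------------------------------------------------
# logos


def test_logo_information_content_closed_forms():
    freq = np.full((15, 20), 1 / 20)
    freq[0] = 0.0
    freq[0, AA20.index("P")] = 1.0  # indicator
    freq[1] = 0.0
    freq[1, AA20.index("P")] = 0.5
    freq[1, AA20.index("R")] = 0.5  # one bit of entropy
    pwm = motifs.PWM(freq)
    heights = export_logo(pwm)
    ic = heights.attrs["ic"]
    assert ic[0] == pytest.approx(np.log2(20))
    assert ic[1] == pytest.approx(np.log2(20) - 1)
    assert ic[2] == pytest.approx(0.0, abs=1e-12)
    assert heights.iloc[2].abs().max() == pytest.approx(0.0, abs=1e-12)
    assert heights.iloc[0]["P"] == pytest.approx(np.log2(20))
    assert heights.iloc[1]["P"] == pytest.approx((np.log2(20) - 1) / 2)


@given(st.integers(0, 2**32 - 1))
def test_logo_heights_bounded_by_ic(seed):
    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.ones(20), size=15)
    heights = export_logo(motifs.PWM(f))
    ic = heights.attrs["ic"]
    assert (ic >= -1e-12).all() and (ic <= np.log2(20) + 1e-12).all()
    assert np.allclose(heights.sum(axis=1), ic)
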