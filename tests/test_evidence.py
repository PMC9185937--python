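"""Template construction and spanning-read classification."""

import numpy as np
import pytest

import mitoforms as mf
from mitoforms.conformations import Conformation, apply_recombination
from mitoforms.evidence import (
    TEMPLATE_KEYS,
    assess_all_pairs,
    build_templates,
    classify_spanning_reads,
)
from mitoforms.genome import revcomp


def _planted(seed, length, plans):
    spec = mf.SimulationSpec(seed=seed, genome_length=length, gc=0.44, repeat_plan=plans)
    g, manifest = mf.generate_genome(spec)
    return g, mf.repeat_pairs_from_manifest(g, manifest)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def test_template_lengths_are_repeat_plus_two_flanks():
    g, pairs = _planted(51, 30_000, [mf.RepeatPlan(78, 100.0, "direct", 5_000, 15_000)])
    ts = build_templates(g, pairs[0], flank=1000)
    assert {len(v) for v in ts.templates().values()} == {2_078}
    assert ts.truncated == {}


def test_template_flank_truncated_by_close_copies():
    g, pairs = _planted(52, 20_000, [mf.RepeatPlan(100, 100.0, "direct", 4_000, 4_700)])
    # arc between copy1 end (4099) and copy2 start (4700) is 600 bp
    ts = build_templates(g, pairs[0], flank=1000)
    assert ts.truncated.get("down1") == 600
    assert ts.truncated.get("up2") == 600
    assert len(ts.ref1) == 1000 + 100 + 600  # up1 full, down1 truncated
    assert len(ts.rec2) == 600 + 100 + 600  # up2 and down1 both truncated
    assert len(ts.rec1) == 1000 + 100 + 1000  # up1 and down2 both full


def test_recombinant_templates_exchange_downstream_flanks():
    g, pairs = _planted(53, 30_000, [mf.RepeatPlan(100, 100.0, "direct", 6_000, 20_000)])
    ts = build_templates(g, pairs[0], flank=800)
    up1, r1, down1 = ts.provenance["ref1"]
    up2, r2, down2 = ts.provenance["ref2"]
    assert ts.rec1 == up1 + r1 + down2
    assert ts.rec2 == up2 + r2 + down1
    # rec1 matches ref1 through flank+repeat, then ref2's downstream
    n = len(up1) + len(r1)
    assert ts.rec1[:n] == ts.ref1[:n]
    assert ts.rec1[n:] == ts.ref2[len(up2) + len(r2) :]


def test_templates_on_inverted_pair_use_repeat_frame():
    g, pairs = _planted(54, 30_000, [mf.RepeatPlan(100, 100.0, "inverted", 6_000, 20_000)])
    ts = build_templates(g, pairs[0], flank=500)
    # both repeat rows are in the aligned frame: identical for an exact pair
    assert ts.provenance["ref1"][1] == ts.provenance["ref2"][1]
    # every template is a substring of the genome in some orientation except
    # the recombinant ones
    doubled = g.seq + g.seq
    both = doubled + revcomp(doubled)
    assert ts.ref1 in both and ts.ref2 in both
    assert ts.rec1 not in both and ts.rec2 not in both


def test_overlapping_copies_have_no_template_geometry():
    g, pairs = _planted(55, 10_000, [mf.RepeatPlan(100, 100.0, "direct", 2_000, 5_000)])
    p = pairs[0]
    p.iv2 = mf.GenomeInterval(2_050, 2_149, "+")
    with pytest.raises(ValueError):
        build_templates(g, p)


# ---------------------------------------------------------------------------
# Spanning-read classification
# ---------------------------------------------------------------------------


def _substring_oracle(reads, ts, anchor):
    """A read supports the unique template whose repeat+anchor window it
    contains verbatim (on either strand)."""
    windows = {k: ts.repeat_window(k, anchor) for k in TEMPLATE_KEYS}
    counts = {k: 0 for k in TEMPLATE_KEYS}
    for _, seq in reads:
        hits = [
            k
            for k, w in windows.items()
            if w in seq or w in revcomp(seq)
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
    return counts


@pytest.fixture(scope="module")
def exact_mixture():
    """Error-free reads from a 50/50 mix of master and fission products."""
    spec = mf.SimulationSpec(
        seed=61,
        genome_length=40_000,
        gc=0.44,
        repeat_plan=[mf.RepeatPlan(150, 100.0, "direct", 8_000, 24_000)],
    )
    g, manifest = mf.generate_genome(spec)
    pair = mf.repeat_pairs_from_manifest(g, manifest)[0]
    split = apply_recombination(Conformation(circles=(g,)), pair)
    circles = [g] + list(split.circles)
    reads, read_manifest = mf.simulate_long_reads(
        circles,
        [0.5, 0.25, 0.25],
        n=200,
        length_mean=6_000,
        length_sd=2_000,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        seed=62,
    )
    ts = build_templates(g, pair, flank=1000)
    return g, pair, ts, reads, read_manifest


def test_error_free_master_reads_support_no_recombinant(planted_genome):
    circle, manifest = planted_genome
    pair = mf.repeat_pairs_from_manifest(circle, manifest)[0]
    ts = build_templates(circle, pair, flank=1000)
    reads, _ = mf.simulate_long_reads(
        [circle], [1.0], n=120, length_mean=5_000, length_sd=1_500,
        sub_rate=0.0, ins_rate=0.0, del_rate=0.0, seed=63,
    )
    sup = classify_spanning_reads(reads, ts)
    assert sup.counts["rec1"] == 0 and sup.counts["rec2"] == 0
    assert sup.verdict == "unsupported"


def test_classifier_equals_substring_oracle_on_error_free_reads(exact_mixture):
    _, _, ts, reads, _ = exact_mixture
    sup = classify_spanning_reads(reads, ts, anchor=100, min_identity=0.70)
    assert sup.counts == _substring_oracle(reads, ts, anchor=100)


def test_mixture_recombinant_fraction_within_three_binomial_se(exact_mixture):
    _, _, ts, reads, _ = exact_mixture
    sup = classify_spanning_reads(reads, ts, anchor=100)
    assert sup.verdict == "supported"
    assert all(sup.counts[k] > 0 for k in TEMPLATE_KEYS)
    n = sum(sup.counts.values())
    frac = sup.recombinant_reads / n
    se = (0.25 / n) ** 0.5
    assert abs(frac - 0.5) <= 3 * se


def test_no_read_double_counted(exact_mixture):
    _, _, ts, reads, _ = exact_mixture
    sup = classify_spanning_reads(reads, ts)
    ids = [r for k in TEMPLATE_KEYS for r in sup.read_ids[k]]
    assert len(ids) == len(set(ids))
    assert sum(sup.counts.values()) <= len(reads)


def test_detection_monotone_in_length_coverage_and_weight():
    """Recombinant support never decreases with longer reads, more reads, or
    a larger recombinant mixture weight (fixed seeds, 3x3 grid)."""
    spec = mf.SimulationSpec(
        seed=64,
        genome_length=40_000,
        gc=0.44,
        repeat_plan=[mf.RepeatPlan(150, 100.0, "direct", 8_000, 24_000)],
    )
    g, manifest = mf.generate_genome(spec)
    pair = mf.repeat_pairs_from_manifest(g, manifest)[0]
    split = apply_recombination(Conformation(circles=(g,)), pair)
    circles = [g] + list(split.circles)
    ts = build_templates(g, pair, flank=1000)

    def rec_count(reads):
        return classify_spanning_reads(reads, ts).recombinant_reads

    # coverage: nested prefixes of one simulation are monotone by counting
    reads, _ = mf.simulate_long_reads(
        circles, [0.4, 0.3, 0.3], n=300, length_mean=5_000, length_sd=1_500,
        sub_rate=0.05, ins_rate=0.025, del_rate=0.025, seed=65,
    )
    by_coverage = [rec_count(reads[:n]) for n in (75, 150, 300)]
    assert by_coverage == sorted(by_coverage)
    # read length
    by_length = []
    for mean in (1_500, 4_000, 8_000):
        r, _ = mf.simulate_long_reads(
            circles, [0.4, 0.3, 0.3], n=150, length_mean=mean, length_sd=mean / 4,
            sub_rate=0.05, ins_rate=0.025, del_rate=0.025, seed=66,
        )
        by_length.append(rec_count(r))
    assert by_length == sorted(by_length)
    # recombinant weight
    by_weight = []
    for w in (0.1, 0.4, 0.8):
        r, _ = mf.simulate_long_reads(
            circles, [1 - w, w / 2, w / 2], n=150, length_mean=5_000, length_sd=1_500,
            sub_rate=0.05, ins_rate=0.025, del_rate=0.025, seed=67,
        )
        by_weight.append(rec_count(r))
    assert by_weight == sorted(by_weight)


def test_zero_reads_all_zero_unsupported(planted_genome):
    circle, manifest = planted_genome
    pair = mf.repeat_pairs_from_manifest(circle, manifest)[0]
    ts = build_templates(circle, pair)
    sup = classify_spanning_reads([], ts)
    assert sup.counts == {k: 0 for k in TEMPLATE_KEYS}
    assert sup.verdict == "unsupported"


def test_assess_all_pairs_flags_only_pairs_with_recombinant_molecules():
    """Of several planted pairs, only those whose recombinant products are in
    the read mixture are called supported."""
    spec = mf.SimulationSpec(
        seed=68,
        genome_length=60_000,
        gc=0.44,
        repeat_plan=[
            mf.RepeatPlan(150, 100.0, "direct", 5_000, 25_000),
            mf.RepeatPlan(150, 100.0, "direct", 35_000, 45_000),
            mf.RepeatPlan(150, 100.0, "direct", 52_000, 57_000),
        ],
    )
    g, manifest = mf.generate_genome(spec)
    pairs = mf.repeat_pairs_from_manifest(g, manifest)
    # recombine only through R1
    split = apply_recombination(Conformation(circles=(g,)), pairs[0])
    circles = [g] + list(split.circles)
    reads, _ = mf.simulate_long_reads(
        circles, [0.5, 0.25, 0.25], n=250, length_mean=5_000, length_sd=1_500,
        sub_rate=0.05, ins_rate=0.025, del_rate=0.025, seed=69,
    )
    supports = assess_all_pairs(g, pairs, reads)
    verdicts = {s.repeat_name: s.verdict for s in supports}
    assert verdicts["R1"] == "supported"
    assert verdicts["R2"] == "unsupported"
    assert verdicts["R3"] == "unsupported"
    assert supports[0].repeat_name == "R1"  # supported pairs sort first
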