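"""Alien Index computation, hit roles, categorization, query processing."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscan import fixtures
from hgtscan.ai_core import (
    CATEGORY_CONTAMINATION,
    CATEGORY_JUNK,
    CATEGORY_NO_HITS,
    CATEGORY_POSSIBLE,
    CATEGORY_VERY_LIKELY,
    ROLE_DONOR,
    ROLE_EXCLUDED,
    ROLE_IGNORED,
    ROLE_RECIPIENT,
    ROLE_UNASSIGNED,
    AIConfig,
    alien_index,
    categorize,
    classify_hit,
    process_query,
    threshold_sweep,
)
from hgtscan.blast_io import BlastHit, QueryBlock

FLOOR = 1e-200
AI_BOUND = math.log((1 + FLOOR) / FLOOR)  # ~460.517


class TestAlienIndex:
    def test_extremes_reach_plus_minus_460_5(self):
        assert round(alien_index(1.0, 0.0), 1) == 460.5
        assert round(alien_index(0.0, 1.0), 1) == -460.5

    def test_equal_evalues_give_zero(self):
        for e in (0.0, 1e-180, 1e-50, 0.5, 1.0):
            assert alien_index(e, e) == 0.0

    def test_worked_scenario_donor_8e81_recipient_9e68(self):
        # frozen from an independent arbitrary-precision evaluation of
        # ln(9e-68 + 1e-200) - ln(8e-81 + 1e-200)
        assert alien_index(9e-68, 8e-81) == pytest.approx(
            30.0513892445789773, abs=1e-9
        )

    def test_donor_only_query_is_50_ln10(self):
        assert alien_index(1.0, 1e-50) == pytest.approx(50 * math.log(10), rel=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.5, 2.0])
    def test_out_of_range_inputs_are_contract_violations(self, bad):
        with pytest.raises(ValueError):
            alien_index(bad, 0.5)
        with pytest.raises(ValueError):
            alien_index(0.5, bad)

    @settings(max_examples=2000, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_antisymmetry_and_bound(self, a, b):
        ai = alien_index(a, b)
        assert ai == -alien_index(b, a)
        assert abs(ai) <= AI_BOUND + 1e-9

    @settings(max_examples=500, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=0.99),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=1e-6, max_value=0.01),
    )
    def test_strict_monotonicity(self, a, b, delta):
        assert alien_index(a + delta, b) > alien_index(a, b)
        assert alien_index(b, a + delta) < alien_index(b, a)


class TestClassifyHit:
    def test_excluded_clade_wins_over_recipient_membership(self, db, config):
        role = classify_hit(fixtures.QUERY_SPECIES_TAXID, config, db)
        assert role.role == ROLE_EXCLUDED

    def test_metazoan_leaf_is_recipient(self, db, config):
        role = classify_hit(fixtures.RECIPIENT_INSECT_TAXID, config, db)
        assert role.role == ROLE_RECIPIENT
        assert role.basal_category == "Eukaryota"

    def test_bacterial_leaf_is_donor(self, db, config):
        role = classify_hit(fixtures.DONOR_BACTERIUM_TAXID, config, db)
        assert role.role == ROLE_DONOR
        assert role.basal_category == "Bacteria"

    def test_other_and_unclassified_are_ignored(self, db, config):
        assert classify_hit(901009, config, db).role == ROLE_IGNORED
        assert classify_hit(901010, config, db).role == ROLE_IGNORED

    def test_unknown_taxid_is_unassigned(self, db, config):
        assert classify_hit(None, config, db).role == ROLE_UNASSIGNED
        assert classify_hit(424242, config, db).role == ROLE_UNASSIGNED

    def test_extra_category_resolves_to_deepest_match(self, db):
        cfg = AIConfig(
            recipient_taxid=33208,
            excluded_taxids=[6300],
            extra_category_taxids=[2759, 4751],  # Eukaryota and nested Fungi
        )
        role = classify_hit(fixtures.DONOR_FUNGUS_TAXID, cfg, db)
        assert role.extra_category == 4751
        assert role.role == ROLE_DONOR  # reporting only, role unchanged


class TestCategorize:
    @pytest.mark.parametrize(
        "ai,identity,expected",
        [
            (31.0, 65.0, CATEGORY_VERY_LIKELY),
            (5.0, 80.0, CATEGORY_CONTAMINATION),
            (-3.0, 50.0, CATEGORY_JUNK),
            (0.0, 50.0, CATEGORY_JUNK),       # AI threshold is strict >
            (30.0, 50.0, CATEGORY_POSSIBLE),  # very-likely threshold strict >
            (5.0, 70.0, CATEGORY_CONTAMINATION),  # identity threshold inclusive >=
            (5.0, 69.99, CATEGORY_POSSIBLE),
            (45.0, 70.0, CATEGORY_CONTAMINATION),  # contamination beats very-likely
        ],
    )
    def test_threshold_semantics(self, ai, identity, expected, config):
        assert categorize(ai, identity, config, has_usable_hits=True) == expected

    def test_no_usable_hits_is_no_hits(self, config):
        assert categorize(None, None, config, has_usable_hits=False) == CATEGORY_NO_HITS


def hit(qid, subject, evalue, identity=50.0, bits=80.0):
    return BlastHit(qid, subject, identity, evalue, bits, f"{qid}\t{subject}\t{evalue}")


class TestProcessQuery:
    def test_zero_hit_block(self, db, config):
        v = process_query(QueryBlock("q0"), config, db)
        assert v.category == CATEGORY_NO_HITS
        assert v.ai is None

    def test_donor_only_block(self, db, config):
        block = QueryBlock("q1", [hit("q1", fixtures.DONOR_SUBJECT, 1e-50)])
        v = process_query(block, config, db)
        assert v.ai == pytest.approx(50 * math.log(10), rel=1e-12)
        assert v.best_recipient_evalue == 1.0  # penalty

    def test_worked_scenario_classifies_very_likely(self, db, config):
        block = QueryBlock(
            "q2",
            [
                hit("q2", fixtures.RECIPIENT_SUBJECT, 9e-68, identity=60.0),
                hit("q2", fixtures.DONOR_SUBJECT, 8e-81, identity=55.0),
                hit("q2", fixtures.EXCLUDED_SUBJECT, 1e-150),
            ],
        )
        v = process_query(block, config, db)
        assert v.ai == pytest.approx(30.0513892445789773, abs=1e-9)
        assert v.category == CATEGORY_VERY_LIKELY
        assert v.best_donor_evalue == 8e-81
        assert v.best_recipient_evalue == 9e-68
        assert v.best_donor_species == "Cellulophaga algicola"

    def test_all_hits_excluded_is_no_hits_not_zero_ai(self, db, config):
        block = QueryBlock(
            "q3",
            [
                hit("q3", fixtures.EXCLUDED_SUBJECT, 1e-80),
                hit("q3", fixtures.UNASSIGNED_SUBJECT, 1e-60),
                hit("q3", fixtures.IGNORED_SUBJECT, 1e-40),
            ],
        )
        v = process_query(block, config, db)
        assert v.category == CATEGORY_NO_HITS
        assert v.ai is None
        assert "excluded" in v.note

    def test_contamination_identity_comes_from_best_donor_hit(self, db, config):
        # best hit overall is a recipient at 95% identity; the donor best
        # is at 40%: identity for the 70% rule must be the donor's
        block = QueryBlock(
            "q4",
            [
                hit("q4", fixtures.RECIPIENT_SUBJECT, 1e-90, identity=95.0),
                hit("q4", fixtures.DONOR_SUBJECT, 1e-95, identity=40.0),
            ],
        )
        v = process_query(block, config, db)
        assert v.best_donor_identity == 40.0
        assert v.category == CATEGORY_POSSIBLE

    def test_best_evalues_ignore_hit_order(self, db, config):
        hits = [
            hit("q5", fixtures.DONOR_SUBJECT, 1e-10),
            hit("q5", fixtures.RECIPIENT_SUBJECT, 9e-68),
            hit("q5", fixtures.DONOR_SUBJECT, 8e-81),
        ]
        for order in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            block = QueryBlock("q5", [hits[i] for i in order])
            v = process_query(block, config, db)
            assert v.best_donor_evalue == 8e-81
            assert v.best_recipient_evalue == 9e-68


# ---- brute-force oracle equivalence ------------------------------------

def brute_force_verdict(block, config, db):
    """Independent re-derivation: full re-scan per question, no streaming."""

    def role_of(h):
        taxid = db.resolve_subject_taxid(h.subject_id)
        if taxid is None:
            return "unassigned"
        lin = db.lineage(db.resolve_merged(taxid))
        if lin is None:
            return "unassigned"
        if any(db.resolve_merged(g) in lin.taxids for g in config.excluded_taxids):
            return "excluded"
        basal = db.basal_category(taxid)
        if basal in ("other", "unclassified"):
            return "ignored"
        if db.resolve_merged(config.recipient_taxid) in lin.taxids:
            return "recipient"
        return "donor"

    recip = [h.evalue for h in block.hits if role_of(h) == "recipient"]
    donor = [h.evalue for h in block.hits if role_of(h) == "donor"]
    usable = bool(recip or donor)
    if not usable:
        return {"ai": None, "category": "no_hits"}
    r = min(recip) if recip else config.penalty_evalue
    d = min(donor) if donor else config.penalty_evalue
    ai = math.log(r + config.evalue_floor) - math.log(d + config.evalue_floor)
    donor_hits = [h for h in block.hits if role_of(h) == "donor"]
    ident = None
    if donor_hits:
        best = min(donor_hits, key=lambda h: (h.evalue, -h.bit_score))
        ident = best.percent_identity
    if ai <= config.ai_possible_threshold:
        cat = "junk"
    elif ident is not None and ident >= config.contamination_identity_threshold:
        cat = "likely_contamination"
    elif ai > config.ai_very_likely_threshold:
        cat = "very_likely"
    else:
        cat = "possible"
    return {"ai": ai, "category": cat, "best_recipient": r, "best_donor": d}


SUBJECT_POOL = [
    fixtures.DONOR_SUBJECT,
    fixtures.RECIPIENT_SUBJECT,
    fixtures.EXCLUDED_SUBJECT,
    fixtures.IGNORED_SUBJECT,
    fixtures.UNASSIGNED_SUBJECT,
    "gi|100004|ref|FUN_001.1|",   # fungal donor
    "gi|100008|ref|ARC_001.1|",   # archaeal donor
    "gi|100002|ref|GRO_001.1|",   # excluded (Tylenchida) relative
    "gi|100013|ref|UNC_001.1|",   # unclassified
]


def random_block(rng, qid):
    n = rng.randint(0, 8)
    hits = []
    for _ in range(n):
        subject = rng.choice(SUBJECT_POOL)
        evalue = rng.choice([0.0, 10.0 ** (-rng.uniform(0, 190)), 1.0])
        hits.append(
            BlastHit(
                qid, subject, round(rng.uniform(20, 99), 2), evalue,
                round(rng.uniform(30, 300), 1), f"{qid}\t{subject}\t{evalue}",
            )
        )
    return QueryBlock(qid, hits)


def test_process_query_matches_brute_force_oracle(db, config):
    rng = random.Random(20240917)
    for i in range(150):
        block = random_block(rng, f"rq{i}")
        v = process_query(block, config, db)
        expect = brute_force_verdict(block, config, db)
        assert v.category == expect["category"], f"block {i}"
        if expect["ai"] is None:
            assert v.ai is None
        else:
            assert v.ai == pytest.approx(expect["ai"], abs=1e-12)
            assert v.best_recipient_evalue == expect["best_recipient"]
            assert v.best_donor_evalue == expect["best_donor"]


def test_excluded_and_ignored_hits_never_change_the_verdict(db, config):
    """Exclusion invariance: decoy insertions leave all results intact."""
    rng = random.Random(99)
    decoy_subjects = [
        fixtures.EXCLUDED_SUBJECT,
        fixtures.IGNORED_SUBJECT,
        fixtures.UNASSIGNED_SUBJECT,
    ]
    for i in range(40):
        block = random_block(rng, f"inv{i}")
        base = process_query(block, config, db)
        decoys = [
            BlastHit(
                block.query_id, rng.choice(decoy_subjects),
                round(rng.uniform(20, 99), 2), 10.0 ** (-rng.uniform(0, 190)),
                round(rng.uniform(30, 300), 1), "decoy",
            )
            for _ in range(rng.randint(1, 4))
        ]
        augmented_hits = list(block.hits)
        for d in decoys:
            augmented_hits.insert(rng.randint(0, len(augmented_hits)), d)
        augmented = process_query(QueryBlock(block.query_id, augmented_hits), config, db)
        assert augmented.ai == base.ai
        assert augmented.best_recipient_evalue == base.best_recipient_evalue
        assert augmented.best_donor_evalue == base.best_donor_evalue
        assert augmented.best_evalue_per_basal == base.best_evalue_per_basal
        if base.category != CATEGORY_NO_HITS:
            assert augmented.category == base.category


class TestThresholdSweep:
    def mk_verdicts(self, ais, db, config):
        out = []
        for i, ai in enumerate(ais):
            d = 1e-60
            r = min(1.0, d * math.exp(ai))
            block = QueryBlock(
                f"t{i}",
                [
                    hit(f"t{i}", fixtures.DONOR_SUBJECT, d),
                    hit(f"t{i}", fixtures.RECIPIENT_SUBJECT, r),
                ],
            )
            out.append(process_query(block, config, db))
        return out

    def test_counts_above_each_threshold(self, db, config):
        verdicts = self.mk_verdicts([-5, 2, 20, 40], db, config)
        rows = threshold_sweep(verdicts, grid=[0, 14, 30])
        assert [r["count"] for r in rows] == [3, 2, 1]

    def test_all_negative_labels_leave_recall_undefined(self, db, config):
        verdicts = self.mk_verdicts([5, -2], db, config)
        labels = {v.query_id: False for v in verdicts}
        (row,) = threshold_sweep(verdicts, grid=[0], labels=labels)
        assert row["recall"] is None
        assert row["false_positive_rate"] == 0.5

    def test_separated_synthetic_set_has_perfect_recall_zero_fpr(self, db, config):
        positives = [20 + i * 0.5 for i in range(50)]
        negatives = [-40 + i * 0.9 for i in range(50)]  # all <= 5
        verdicts = self.mk_verdicts(positives + negatives, db, config)
        labels = {v.query_id: i < 50 for i, v in enumerate(verdicts)}
        (row,) = threshold_sweep(verdicts, grid=[14], labels=labels)
        assert row["recall"] == 1.0
        assert row["false_positive_rate"] == 0.0

    def test_empty_grid_is_rejected(self, db, config):
        with pytest.raises(ValueError):
            threshold_sweep([], grid=[])


class TestAIConfigValidation:
    def test_empty_exclusion_list_is_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            AIConfig(recipient_taxid=33208, excluded_taxids=[])

    def test_floor_must_sit_below_penalty(self):
        with pytest.raises(ValueError):
            AIConfig(recipient_taxid=33208, excluded_taxids=[6300], evalue_floor=2.0)
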