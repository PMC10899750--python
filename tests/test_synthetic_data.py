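"""Simulator: library enumeration, cleavage model, read emission."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicerscan import synthetic_data as sd
from dicerscan.read_processing import split_two_loop, strip_adapters, trim_ends


class TestLibraryEnumeration:
    def test_single_group_yields_4096(self, design):
        one = sd.LibraryDesign(window_starts=(14,))
        variants = sd.build_variant_library(one)
        assert len(variants) == 4096
        assert len({v.sequence for v in variants}) == 4096

    def test_six_group_union_is_23296(self, unique_library):
        unique, index = unique_library
        assert len(unique) == 23296
        assert len(index) == 23296

    def test_closed_form_matches_enumeration(self, design, unique_library):
        assert sd.expected_unique_count(design) == len(unique_library[0])

    def test_disjoint_windows_share_only_backbone(self):
        two = sd.LibraryDesign(window_starts=(14, 17))
        unique, _ = sd.dedup_reference(sd.build_variant_library(two))
        assert len(unique) == 2 * 4096 - 1
        assert sd.expected_unique_count(two) == 2 * 4096 - 1

    def test_brute_force_set_oracle(self):
        # independent oracle: enumerate full sequences directly as a set
        two = sd.LibraryDesign(window_starts=(15, 16))
        oracle = set()
        for start in two.window_starts:
            for combo in itertools.product(sd.DNA, repeat=6):
                oracle.add(
                    sd.variant_sequence(two, start, "".join(combo[:3]), "".join(combo[3:]))
                )
        unique, _ = sd.dedup_reference(sd.build_variant_library(two))
        assert len(unique) == len(oracle)
        assert sd.expected_unique_count(two) == len(oracle)

    @given(starts=st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=4, unique=True))
    @settings(max_examples=15, deadline=None)
    def test_closed_form_matches_any_layout(self, starts):
        d = sd.LibraryDesign(window_starts=tuple(sorted(starts)))
        unique, _ = sd.dedup_reference(sd.build_variant_library(d))
        assert sd.expected_unique_count(d) == len(unique)

    def test_window_outside_backbone_is_configuration_error(self):
        with pytest.raises(sd.DesignError):
            sd.LibraryDesign(window_starts=(21,))  # 21..23 > 22-bp stem

    def test_variant_reconstructs_deterministically(self, design, library):
        v = library[123]
        assert v.sequence == sd.variant_sequence(design, v.window_start, v.fill5, v.fill3)
        assert v.fill == v.fill5 + v.fill3


class TestDesignLayout:
    def test_backbone_is_fully_paired(self, design):
        backbone = design.backbone_sequence()
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for i in range(1, design.stem_len + 1):
            assert backbone[design.partner(i) - 1] == comp[backbone[i - 1]]

    def test_delimiters_absent_from_backbone(self, design):
        backbone = design.backbone_sequence()
        assert design.loop_delim_left not in backbone
        assert design.loop_delim_right not in backbone

    def test_design_dotbracket_of_backbone_is_perfect_hairpin(self, design, library):
        wild = next(v for v in library if v.sequence == design.backbone_sequence())
        db = sd.design_dotbracket(design, wild)
        assert db == "(" * 22 + "." * 26 + ")" * 22

    def test_mismatch_fill_unpairs_its_position(self, design):
        v = sd.ShRNAVariant("x", 4, 17, "ACA", "ACA", sd.variant_sequence(design, 17, "ACA", "ACA"))
        db = sd.design_dotbracket(design, v)
        # A-A at 17 and 19 unpaired, C-C at 18 unpaired
        assert db[16:19] == "..."
        assert db[design.partner(19) - 1 : design.partner(17)] == "..."


class TestCleavageModel:
    def test_zero_betas_give_identical_distribution(self, design, library):
        model = sd.CleavageModel()
        a = sd.simulate_cleavage(library[0], model, design)
        b = sd.simulate_cleavage(library[999], model, design)
        assert a == pytest.approx(b)

    def test_probabilities_sum_to_one(self, design, library):
        model = sd.CleavageModel(beta_mwcu=1.0, beta_ycr=0.7, ycr_sc_suppression=0.5)
        for v in library[:50]:
            p = sd.simulate_cleavage(v, model, design)
            assert sum(p.values()) == pytest.approx(1.0)

    def test_dsrbd_gate_zeroes_mwcu_effect(self, design):
        # 17-mWCU: W at 17, C-C at 18, T-containing pair at 19
        fill5, fill3 = "ACT", "TCA"
        v = sd.ShRNAVariant("m", 4, 17, fill5, fill3, sd.variant_sequence(design, 17, fill5, fill3))
        wt = sd.simulate_cleavage(v, sd.CleavageModel(beta_mwcu=2.0, enzyme="WT"), design)
        mut = sd.simulate_cleavage(v, sd.CleavageModel(beta_mwcu=2.0, enzyme="dsRBD_del"), design)
        base = sd.simulate_cleavage(v, sd.CleavageModel(), design)
        assert mut == pytest.approx(base)
        assert wt[("DC", 21)] > base[("DC", 21)]

    def test_r1855a_gates_like_dsrbd_del_and_e1859a_attenuates(self, design):
        fill5, fill3 = "ACT", "TCA"
        v = sd.ShRNAVariant("m", 4, 17, fill5, fill3, sd.variant_sequence(design, 17, fill5, fill3))
        kw = dict(beta_mwcu=2.0)
        p = {
            enz: sd.simulate_cleavage(v, sd.CleavageModel(enzyme=enz, **kw), design)[("DC", 21)]
            for enz in ("WT", "dsRBD_del", "R1855A", "E1859A")
        }
        assert p["R1855A"] == pytest.approx(p["dsRBD_del"])
        assert p["dsRBD_del"] < p["E1859A"] < p["WT"]

    def test_large_beta_ycr_drives_target_site_to_max(self, design):
        # 19-YCR: Y-containing pair at 19, C-G at 20, R-Y at 21 -> DC21
        fill5, fill3 = "TCG", "AGC"
        v = sd.ShRNAVariant("y", 6, 19, fill5, fill3, sd.variant_sequence(design, 19, fill5, fill3))
        assert sd.is_ycr_pattern(v.fill)
        probs = sd.simulate_cleavage(v, sd.CleavageModel(beta_ycr=30.0), design)
        dc = {s: probs[("DC", s)] for s in sd.SITES}
        assert max(dc, key=dc.get) == 21
        assert dc[21] / sum(dc.values()) > 0.99

    def test_ycr_suppresses_single_cleavage(self, design):
        fill5, fill3 = "TCG", "AGC"
        v = sd.ShRNAVariant("y", 6, 19, fill5, fill3, sd.variant_sequence(design, 19, fill5, fill3))
        base = sd.simulate_cleavage(v, sd.CleavageModel(), design)
        supp = sd.simulate_cleavage(v, sd.CleavageModel(ycr_sc_suppression=2.0), design)
        sc = lambda p: sum(v for (m, _), v in p.items() if m != "DC")
        assert sc(supp) < sc(base)

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError):
            sd.CleavageModel(enzyme="T7")


@pytest.fixture(scope="module")
def truth(design, unique_library):
    variants = sd.subset_variants(unique_library[0], 5, seed=11)
    model = sd.CleavageModel(sc_logit=-0.5)
    return sd.simulate_library(variants, model, design, n_reads=60, seed=11, os_reads=10)


class TestEmitReads:
    def test_counts_are_multinomial_totals(self, truth):
        for v in truth.variants:
            assert sum(truth.counts[v.variant_id].values()) == 60

    def test_same_seed_is_byte_identical(self, truth, design, tmp_path):
        p1 = sd.emit_reads(truth, design, tmp_path / "a")
        p2 = sd.emit_reads(truth, design, tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_zero_reads_is_valid_empty_fastq(self, design, unique_library, tmp_path):
        variants = sd.subset_variants(unique_library[0], 2, seed=1)
        truth = sd.simulate_library(variants, sd.CleavageModel(), design, n_reads=0, seed=1, os_reads=0)
        paths = sd.emit_reads(truth, design, tmp_path)
        for p in paths.values():
            assert p.read_text() == ""

    def test_forced_dc_read_is_expected_substring(self, design, tmp_path):
        """A DC read at x=21 carries substrate positions 22..51 around the
        barcode loop, recoverable by adapter/UMI/loop removal."""
        v = sd.ShRNAVariant("w", 1, 14, "TGC", "GCA", sd.variant_sequence(design, 14, "TGC", "GCA"))
        truth = sd.simulate_library([v], sd.CleavageModel(), design, n_reads=0, seed=5, os_reads=0)
        truth.counts[v.variant_id][("DC", 21)] = 1
        paths = sd.emit_reads(truth, design, tmp_path)
        lines = paths["dc"].read_text().splitlines()
        assert len(lines) == 4
        seq = strip_adapters(lines[1], design.adapter3, design.adapter5)
        umi5, body, umi3 = trim_ends(seq, design.dc_umi5_len, design.umi3_len)
        cp, barcode = split_two_loop(body, design.loop_delim_left, design.loop_delim_right)
        assert cp == v.sequence[21:51]
        assert barcode in truth.barcodes[v.variant_id]

    def test_ground_truth_tsv_round_trips(self, truth, design, tmp_path):
        import pandas as pd

        path = tmp_path / "truth.tsv"
        sd.write_ground_truth(truth, path)
        frame = pd.read_csv(path, sep="\t")
        assert len(frame) == len(truth.variants) * len(sd.CATEGORIES)
        total = frame.groupby("variant_id")["count"].sum()
        assert (total == 60).all()


class TestGradedEffects:
    def test_effects_cover_all_fills_and_boost_pattern(self):
        eff = sd.graded_motif_effects(seed=0, motif_class="mWCU")
        assert len(eff) == 4096
        planted = [v for k, v in eff.items() if sd.is_mwcu_pattern(k)]
        controls = [v for k, v in eff.items() if not sd.is_mwcu_pattern(k)]
        assert min(planted) > np.mean(controls)

    def test_deterministic(self):
        assert sd.graded_motif_effects(3, "YCR") == sd.graded_motif_effects(3, "YCR")
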