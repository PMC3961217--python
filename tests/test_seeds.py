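"""Seed extraction, site scanning vs a brute-force oracle, DE overlap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from senscreen import (
    MatureMiRNA,
    extract_seed,
    genes_with_sites,
    overlap_with_de,
    scan_sites,
    simulate_utrs,
)

MIRNA = MatureMiRNA("miR-test", "CUCCUGACUCCAGGUCCUGUGU")  # seed UCCUGAC -> TCCTGAC

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_sites(utr: str, mirna: MatureMiRNA) -> set:
    """Independent oracle: slide every window and apply the site-type
    definitions literally (hand-rolled complementing, no shared code
    with the scanner)."""
    seq = utr.upper().replace("U", "T")
    seed7 = mirna.sequence[1:8]
    rc7 = "".join(_COMP[b] for b in reversed(seed7))
    rc6 = "".join(_COMP[b] for b in reversed(seed7[:6]))
    m8 = rc7[0]
    L = len(seq)
    out = set()
    for i in range(L):
        if seq[i : i + 8] == rc7 + "A":
            out.add((i, i + 8, "8mer"))
        if seq[i : i + 7] == rc7 and seq[i + 7 : i + 8] != "A":
            out.add((i, i + 7, "7mer-m8"))
        if seq[i : i + 7] == rc6 + "A" and (i == 0 or seq[i - 1] != m8):
            out.add((i, i + 7, "7mer-A1"))
        if (
            seq[i : i + 6] == rc6
            and (i == 0 or seq[i - 1] != m8)
            and (i + 6 == L or seq[i + 6] != "A")
        ):
            out.add((i, i + 6, "6mer"))
    return out


def as_set(sites):
    return {(s.start, s.end, s.site_type) for s in sites}


class TestExtractSeed:
    def test_seed_is_positions_2_to_8(self):
        assert extract_seed(MIRNA) == "TCCTGAC"
        assert len(extract_seed("AUCACUUAAGGCAUCACUUA")) == 7

    def test_u_and_t_inputs_agree(self):
        u = extract_seed("AUCACUUAAGGCAUCACUUA")
        t = extract_seed("ATCACTTAAGGCATCACTTA")
        assert u == t

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_seed("AUCACU")

    def test_mature_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            MatureMiRNA("short", "AUCACUUAAGGCAUC")  # 15 nt
        with pytest.raises(ValueError):
            MatureMiRNA("bad", "AUCACUUAAGGCAUCACUXA")


class TestScanSites:
    def test_no_core_match_yields_empty(self):
        assert scan_sites("A" * 50, MIRNA) == []

    @pytest.mark.parametrize(
        "stype,length", [("8mer", 8), ("7mer-m8", 7), ("7mer-A1", 7), ("6mer", 6)]
    )
    def test_planted_site_found_with_exact_type(self, rng, stype, length):
        utrs, _ = simulate_utrs(1, 120, [(0, 40, stype)], extract_seed(MIRNA), rng)
        sites = scan_sites(utrs["tx0001"], MIRNA, "tx0001")
        assert as_set(sites) == {(40, 40 + length, stype)}

    def test_boundary_sites(self):
        rc7 = "GTCAGGA"  # reverse complement of TCCTGAC
        rc6 = "TCAGGA"
        # m8 match flush at the 5' start: no room for more, types as 7mer-m8
        sites = scan_sites(rc7 + "C" * 10, MIRNA)
        assert (0, 7, "7mer-m8") in as_set(sites)
        # core at the very 3' end with the A1 position off the sequence: 6mer
        sites = scan_sites("C" * 10 + rc6, MIRNA)
        assert as_set(sites) == {(10, 16, "6mer")}
        # A1 adenosine at position 0 is impossible; core flush at start is 6mer/7mer-A1
        sites = scan_sites(rc6 + "A" + "C" * 10, MIRNA)
        assert as_set(sites) == {(0, 7, "7mer-A1")}

    def test_each_core_reported_once_under_strongest_type(self):
        rc7 = "GTCAGGA"
        utr = "CC" + rc7 + "A" + "CC"  # 8mer context: rc7 starts at 2
        assert as_set(scan_sites(utr, MIRNA)) == {(2, 10, "8mer")}

    def test_n_windows_never_match(self):
        utr = "CCGTCAGGNACC"
        assert scan_sites(utr, MIRNA) == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_sites("ACGTXACGT", MIRNA)

    def test_additivity_over_nonmatching_spacer(self, rng):
        utrs, _ = simulate_utrs(
            2, 80, [(0, 20, "8mer"), (1, 50, "7mer-A1")], extract_seed(MIRNA), rng
        )
        a, b = utrs["tx0001"], utrs["tx0002"]
        spacer = "C" * 10
        combined = as_set(scan_sites(a + spacer + b, MIRNA))
        expected = as_set(scan_sites(a, MIRNA)) | {
            (s + len(a) + 10, e + len(a) + 10, t) for s, e, t in as_set(scan_sites(b, MIRNA))
        }
        assert combined == expected

    def test_oracle_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(2024)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            utr = "".join(rng.choice(bases, size=200))
            assert as_set(scan_sites(utr, MIRNA)) == brute_force_sites(utr, MIRNA)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=60), st.integers(0, 3))
    def test_oracle_equivalence_property(self, utr, which):
        mirna = [
            MIRNA,
            MatureMiRNA("a", "AAAAGCUGGAGUUCAAACGU"),
            MatureMiRNA("b", "UGAGGUAGUAGGUUGUAUAGUU"),  # let-7-like
            MatureMiRNA("c", "ACGCGCGCGAUAUAUACGCG"),
        ][which]
        assert as_set(scan_sites(utr, mirna)) == brute_force_sites(utr, mirna)

    def test_antisense_mirror_cross_check(self, rng):
        """Core-match starts on the sense strand mirror the occurrences of
        the T-normalized seed 6-mer on the reverse complement strand."""
        from Bio.Seq import Seq

        utrs, _ = simulate_utrs(
            3, 150, [(0, 30, "8mer"), (1, 70, "6mer")], extract_seed(MIRNA), rng
        )
        seed6 = extract_seed(MIRNA)[:6]
        for tx, utr in utrs.items():
            rc = str(Seq(utr).reverse_complement())
            antisense_hits = {
                i for i in range(len(rc) - 5) if rc[i : i + 6] == seed6
            }
            mirrored = {len(utr) - 6 - i for i in antisense_hits}
            core_starts = set()
            for s in scan_sites(utr, MIRNA, tx):
                core_starts.add(s.start + 1 if s.site_type in ("8mer", "7mer-m8") else s.start)
            assert core_starts == mirrored


class TestGenesWithSites:
    def test_empty_input_empty_set(self):
        assert genes_with_sites({}, MIRNA) == set()

    def test_planted_genes_recovered_exactly(self, rng):
        planted = [(i, 40 + 7 * i, "7mer-m8") for i in range(0, 30)]
        utrs, _ = simulate_utrs(200, 400, planted, extract_seed(MIRNA), rng)
        expected = {f"tx{i + 1:04d}" for i in range(30)}
        assert genes_with_sites(utrs, MIRNA) == expected

    def test_min_type_monotonicity(self, rng):
        planted = [(0, 40, "8mer"), (1, 40, "7mer-m8"), (2, 40, "6mer")]
        utrs, _ = simulate_utrs(5, 200, planted, extract_seed(MIRNA), rng)
        sets = [genes_with_sites(utrs, MIRNA, min_type=t) for t in ("6mer", "7mer-A1", "7mer-m8", "8mer")]
        for weaker, stronger in zip(sets, sets[1:]):
            assert stronger <= weaker
        assert sets[0] == {"tx0001", "tx0002", "tx0003"}
        assert sets[3] == {"tx0001"}

    def test_transcript_to_gene_mapping(self, rng):
        utrs, _ = simulate_utrs(2, 100, [(0, 30, "8mer")], extract_seed(MIRNA), rng)
        mapping = {"tx0001": "GENE_A", "tx0002": "GENE_B"}
        assert genes_with_sites(utrs, MIRNA, mapping) == {"GENE_A"}

    def test_duplicate_transcript_ids_rejected(self, tmp_path):
        fasta = tmp_path / "dup.fa"
        fasta.write_text(">tx1\nACGT\n>tx1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            genes_with_sites(str(fasta), MIRNA)


class TestOverlap:
    def test_disjoint_sets_zero_counts_with_warning(self):
        with pytest.warns(UserWarning, match="namespace"):
            rep = overlap_with_de({"a", "b"}, {"c"}, {"d"})
        assert rep.n_up_and_target == 0 and rep.n_down_and_target == 0

    def test_subset_intersection(self):
        rep = overlap_with_de({"a", "b", "c"}, set(), {"a", "b"})
        assert rep.n_down_and_target == 2
        m = rep.membership.set_index("gene")
        assert bool(m.loc["a", "in_targets"]) and bool(m.loc["a", "in_de_down"])

    def test_membership_reproduces_counts(self):
        rep = overlap_with_de({"a", "b", "c"}, {"b", "x"}, {"c", "y"})
        m = rep.membership
        assert (m["in_targets"] & m["in_de_up"]).sum() == rep.n_up_and_target
        assert (m["in_targets"] & m["in_de_down"]).sum() == rep.n_down_and_target
        assert m["in_targets"].sum() == rep.n_targets
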