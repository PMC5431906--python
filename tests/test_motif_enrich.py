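"""PWM scanning vs brute force, densities, rank statistics, 3'-end signals."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from cgsplice.annotations import Exon, Gene, GenomeAnnotation, Transcript
from cgsplice.motif_enrich import (
    CG_REGIONS,
    PWM,
    SE_REGIONS,
    background_frequencies,
    cluster_motif_patterns,
    dedup_motif_families,
    density_enrichment,
    extract_cg_regions,
    extract_se_regions,
    find_polya_signals,
    is_dse,
    motif_density,
    read_pwm_file,
    scan_pwm,
    write_pwm_file,
)


def brute_force_scan(seq, pwm, threshold_frac=0.8, background=None):
    """Independent all-windows scorer (plain Python, no vectorization)."""
    bg = background if background is not None else pwm.background
    L = len(pwm)
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    max_score = sum(
        max(math.log2(max(pwm.matrix[i, b], 1e-300) / bg[b]) for b in range(4))
        for i in range(L)
    )
    hits = []
    s = seq.upper()
    for start in range(len(s) - L + 1):
        window = s[start : start + L]
        if any(ch not in code for ch in window):
            continue
        score = sum(
            math.log2(max(pwm.matrix[i, code[ch]], 1e-300) / bg[code[ch]])
            for i, ch in enumerate(window)
        )
        if score >= threshold_frac * max_score - 1e-12:
            hits.append(start)
    return hits


class TestScanPwm:
    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        pwms = [
            PWM.from_consensus("TGCATG", id="hard"),
            PWM(
                id="soft", rbp_name="soft", family="soft",
                matrix=rng.dirichlet(np.ones(4) * 2, size=5),
            ),
        ]
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=200, p=[0.24] * 4 + [0.04]))
            for pwm in pwms:
                fast = scan_pwm(seq, pwm).tolist()
                assert fast == brute_force_scan(seq, pwm)

    def test_hard_consensus_matches_only_exact_windows(self):
        pwm = PWM.from_consensus("TGCATG")
        seq = "TGCATG" + "A" * 20 + "TGCATC" + "TGCATG"
        assert scan_pwm(seq, pwm).tolist() == [0, 32]

    def test_too_short_sequence_empty(self):
        assert scan_pwm("ACG", PWM.from_consensus("TGCATG")).size == 0

    def test_single_exact_match(self):
        assert scan_pwm("TGCATG", PWM.from_consensus("TGCATG")).tolist() == [0]

    def test_u_and_t_equivalent(self):
        pwm = PWM.from_consensus("UGCAUG")
        assert scan_pwm("TGCATG", pwm).tolist() == [0]


class TestDensity:
    @pytest.mark.parametrize("m,l,d", [(2, 100, 0.02), (0, 50, 0.0), (3, 150, 0.02)])
    def test_density_arithmetic(self, m, l, d):
        assert motif_density(m, l) == pytest.approx(d)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            motif_density(1, 0)


def density_frame(region, motif, values):
    return pd.DataFrame({"region": region, "motif_id": motif, "density": values})


class TestDensityEnrichment:
    def test_complete_separation_effect_plus_one(self):
        g = density_frame("SE", "m1", np.linspace(0.5, 0.9, 20))
        o = density_frame("SE", "m1", np.linspace(0.0, 0.4, 50))
        out = density_enrichment(g, o)
        assert out.iloc[0]["effect"] == pytest.approx(1.0)
        assert out.iloc[0]["significant"]

    def test_single_test_adjusted_equals_raw(self):
        rng = np.random.default_rng(1)
        g = density_frame("SE", "m1", rng.uniform(size=10))
        o = density_frame("SE", "m1", rng.uniform(size=10))
        out = density_enrichment(g, o)
        assert out.iloc[0]["p_adj"] == pytest.approx(out.iloc[0]["p"])

    def test_rank_biserial_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = rng.normal(0.5, 1, size=15)
            o = rng.normal(0.0, 1, size=25)
            out = density_enrichment(
                density_frame("SE", "m1", g), density_frame("SE", "m1", o)
            )
            u_other = mannwhitneyu(o, g, alternative="two-sided").statistic
            assert out.iloc[0]["effect"] == pytest.approx(
                1 - 2 * u_other / (len(g) * len(o))
            )

    def test_identical_constants_give_null_cell(self):
        g = density_frame("SE", "m1", np.zeros(5))
        o = density_frame("SE", "m1", np.zeros(9))
        out = density_enrichment(g, o)
        assert out.iloc[0]["p"] == 1.0 and out.iloc[0]["effect"] == 0.0

    def test_small_group_rejected(self):
        g = density_frame("SE", "m1", [0.1, 0.2])
        o = density_frame("SE", "m1", [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            density_enrichment(g, o)

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(3)
        regions = [f"r{i}" for i in range(8)]
        g = pd.concat(
            [density_frame(r, "m1", rng.uniform(size=10)) for r in regions]
        )
        o = pd.concat(
            [density_frame(r, "m1", rng.uniform(size=10)) for r in regions]
        )
        out = density_enrichment(g, o).sort_values("p")
        assert (np.diff(out["p_adj"]) >= -1e-12).all()
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestFamilyDedup:
    def cells(self, rows):
        return pd.DataFrame(rows, columns=["motif_id", "region", "significant"])

    def test_most_regions_wins(self):
        cells = self.cells(
            [("m1", r, True) for r in ("a", "b", "c")] + [("m2", "a", True)]
        )
        fam = {"m1": "F", "m2": "F"}
        assert dedup_motif_families(cells, fam) == ["m1"]

    def test_representative_member_wins_regardless(self):
        cells = self.cells(
            [("m1", r, True) for r in ("a", "b", "c")] + [("m2", "a", True)]
        )
        fam = {"m1": "F", "m2": "F"}
        assert dedup_motif_families(cells, fam, {"F": "m2"}) == ["m2"]

    def test_tie_breaks_lexicographically(self):
        cells = self.cells([("mB", "a", True), ("mA", "b", True)])
        fam = {"mA": "F", "mB": "F"}
        assert dedup_motif_families(cells, fam) == ["mA"]

    def test_uncovered_motif_rejected(self):
        cells = self.cells([("m1", "a", True)])
        with pytest.raises(ValueError):
            dedup_motif_families(cells, {})


class TestPatternClustering:
    def test_identical_rows_cluster_together(self):
        m = pd.DataFrame([[1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]], index=list("abc"))
        labels = cluster_motif_patterns(m)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_all_identical_single_cluster(self):
        m = pd.DataFrame([[0.5, 0.5]] * 4, index=list("abcd"))
        assert cluster_motif_patterns(m).nunique() == 1

    def test_antipodal_pairs_form_two_clusters(self):
        m = pd.DataFrame(
            [[1.0, 1.0], [0.9, 1.1], [-1.0, -1.0], [-1.1, -0.9]],
            index=list("abcd"),
        )
        labels = cluster_motif_patterns(m)
        assert labels["a"] == labels["b"] != labels["c"]
        assert labels["c"] == labels["d"]

    def test_single_motif_single_cluster(self):
        m = pd.DataFrame([[1.0, 0.0]], index=["a"])
        assert cluster_motif_patterns(m).tolist() == [1]


class TestPwmFile:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        pwms = [
            PWM.from_consensus("TGCATG", id="m1", rbp_name="RBFOX", family="Fox"),
            PWM(id="m2", rbp_name="X", family="Y", matrix=rng.dirichlet(np.ones(4), 4)),
        ]
        p = tmp_path / "pwms.txt"
        write_pwm_file(pwms, p)
        back = read_pwm_file(p)
        assert [b.id for b in back] == ["m1", "m2"]
        for a, b in zip(pwms, back):
            assert (a.rbp_name, a.family) == (b.rbp_name, b.family)
            assert np.allclose(a.matrix, b.matrix, atol=1e-5)


class SEEvent:
    def __init__(self, chrom, strand, upstream_exon, se, downstream_exon):
        self.chrom, self.strand = chrom, strand
        self.upstream_exon, self.se, self.downstream_exon = upstream_exon, se, downstream_exon


class TestRegionExtraction:
    def genome(self, n=5000, seed=5):
        rng = np.random.default_rng(seed)
        return {"chr1": "".join(rng.choice(list("ACGT"), n))}

    def test_long_intron_capped_at_splice_sites(self):
        g = self.genome()
        ev = SEEvent("chr1", "+", (0, 100), (1100, 1200), (2200, 2300))
        regions = extract_se_regions(ev, g, intron_cap=600)
        assert set(regions) == set(SE_REGIONS)
        seq = g["chr1"]
        assert regions["up5in"] == seq[100:400]       # 300 bp after the up exon
        assert regions["up3in"] == seq[800:1100]      # 300 bp before the SE
        assert regions["SE"] == seq[1100:1200]
        assert regions["dn5in"] == seq[1200:1500]
        assert regions["dn3in"] == seq[1900:2200]

    def test_short_intron_split_at_midpoint(self):
        g = self.genome()
        ev = SEEvent("chr1", "+", (0, 100), (200, 300), (400, 500))
        regions = extract_se_regions(ev, g, intron_cap=600)
        seq = g["chr1"]
        assert regions["up5in"] == seq[100:150]
        assert regions["up3in"] == seq[150:200]

    def test_minus_strand_orientation(self):
        g = self.genome()
        ev = SEEvent("chr1", "-", (2200, 2300), (1100, 1200), (0, 100))
        regions = extract_se_regions(ev, g, intron_cap=600)
        comp = str.maketrans("ACGT", "TGCA")
        seq = g["chr1"]
        assert regions["SE"] == seq[1100:1200].translate(comp)[::-1]
        # up5in abuts the (genomic right) upstream exon's splice site
        assert regions["up5in"] == seq[1900:2200].translate(comp)[::-1]

    def test_cg_regions_pick_terminal_exons(self, small_study):
        planted = small_study["planted"][0]
        regions = extract_cg_regions(
            planted, small_study["ann"], small_study["genome"]
        )
        assert set(regions) == set(CG_REGIONS)
        up_tx = small_study["ann"].genes[planted.upstream_gene].longest_transcript()
        e = up_tx.exons[-1]
        assert regions["last_exon"] == small_study["genome"]["chr1"][e.start:e.end]

    def test_single_exon_partner_rejected(self):
        ann = GenomeAnnotation()
        u = Gene(id="U", chrom="chr1", strand="+")
        u.transcripts["t"] = Transcript(id="t", gene_id="U", exons=[Exon("chr1", 0, 100, "+")])
        d = Gene(id="D", chrom="chr1", strand="+")
        d.transcripts["t2"] = Transcript(
            id="t2", gene_id="D",
            exons=[Exon("chr1", 200, 300, "+"), Exon("chr1", 400, 500, "+")],
        )
        ann.genes["U"], ann.genes["D"] = u, d

        class CG:
            upstream_gene, downstream_gene = "U", "D"

        from cgsplice.annotations import AnnotationError

        with pytest.raises(AnnotationError):
            extract_cg_regions(CG(), ann, {"chr1": "A" * 600})


def dse_oracle(seq):
    """Enumerate every window of length >= 6 and apply the rule literally."""
    s = seq.upper().replace("T", "U")
    for i in range(len(s)):
        for j in range(i + 6, len(s) + 1):
            w = s[i:j]
            if all(ch in "UG" for ch in w) and "GG" not in w and w.count("G") <= 3:
                return True
    return False


class TestDse:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("UUUUUU", True),
            ("UUGGUU", False),
            ("UGUGUUU", True),
            ("ACGUAC", False),
            ("UGUGUG", True),
            ("GUGUGU", True),
        ],
    )
    def test_rule_examples(self, seq, expected):
        assert is_dse(seq) is expected

    @settings(max_examples=300, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=0, max_size=30))
    def test_matches_enumeration_oracle(self, seq):
        assert is_dse(seq) == dse_oracle(seq)


class TestPolyASignals:
    def gene_at(self, end, strand="+"):
        g = Gene(id="g", chrom="chr1", strand=strand)
        g.transcripts["t"] = Transcript(
            id="t", gene_id="g", exons=[Exon("chr1", 0, end, strand)]
        )
        return g

    def test_canonical_hexamers(self):
        for hexamer, expected in [("AATAAA", True), ("ATTAAA", True), ("AGTAAA", False)]:
            genome = {"chr1": "C" * 94 + hexamer + "C" * 100}
            rep = find_polya_signals(self.gene_at(100), 100, genome)
            assert rep.canonical_signal is expected

    def test_ugua_window_wider_than_signal_window(self):
        genome = {"chr1": "C" * 30 + "TGTA" + "C" * 116 + "C" * 50}
        rep = find_polya_signals(self.gene_at(150), 150, genome)
        assert rep.ugua_count == 1 and not rep.canonical_signal

    def test_downstream_dse_detected(self):
        genome = {"chr1": "C" * 100 + "GCTTGTTGTTGC" + "C" * 40}
        rep = find_polya_signals(self.gene_at(100), 100, genome)
        assert rep.dse

    def test_out_of_bounds_site_rejected(self):
        from cgsplice.annotations import AnnotationError

        with pytest.raises(AnnotationError):
            find_polya_signals(self.gene_at(100), 10**6, {"chr1": "A" * 200})

    def test_minus_strand_windows_are_reverse_complemented(self):
        # on the minus strand "upstream" lies at higher genomic coordinates
        genome = {"chr1": "C" * 100 + "TTTATT" + "C" * 94}
        rep = find_polya_signals(self.gene_at(200, strand="-"), 100, genome)
        assert rep.canonical_signal  # revcomp(TTTATT) = AATAAA


class TestBackgroundFrequencies:
    def test_pooled_frequencies(self):
        bg = background_frequencies(["AACC", "GGTT"])
        assert bg.tolist() == pytest.approx([0.25, 0.25, 0.25, 0.25])

    def test_empty_input_uniform(self):
        assert background_frequencies([]).tolist() == [0.25] * 4
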