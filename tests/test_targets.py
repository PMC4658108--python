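"""UTR transfer rules, seed-site prediction vs brute force, tallies, trends."""

import numpy as np
import pandas as pd
import pytest

from mirseek.seq import revcomp
from mirseek.targets import (UTRRecord, compare_target_expression,
                             predict_all, predict_targets, tally_pathways,
                             target_counts, transfer_utrs, unigene_utrs)

RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _genome_with(rng, utr, offset, n=4000):
    g = _random_seq(rng, n)
    return g[:offset] + utr + g[offset + len(utr):]


class TestTransferUTRs:
    def _setup(self, seed=0, utr_len=100, offset=2000):
        rng = np.random.default_rng(seed)
        utr = _random_seq(rng, utr_len)
        genome = _genome_with(rng, utr, offset)
        gene_ends = pd.DataFrame({"name": ["gene1"], "end": [offset - 50]})
        return utr, genome, gene_ends

    def test_exact_copy_near_gene_end_transfers(self, config):
        utr, genome, ends = self._setup()
        records = transfer_utrs({"donor1": utr}, genome, ends, config)
        assert len(records) == 1
        rec = records[0]
        assert rec.gene == "gene1"
        assert rec.sequence == utr
        assert rec.source == "transferred"
        assert rec.distance_to_gene_end <= config.utr_proximity

    def test_two_mismatches_accepted_three_rejected(self, config):
        utr, genome, ends = self._setup(seed=1)
        # mismatches inside the intersection of all 80% windows, so no
        # sub-window can dodge them
        lo = int(0.2 * len(utr))
        positions = [lo + 10, len(utr) // 2, len(utr) - lo - 10]
        mutate = lambda s, ps: "".join(RC[c] if i in ps else c
                                       for i, c in enumerate(s))
        two = mutate(utr, set(positions[:2]))
        three = mutate(utr, set(positions))
        assert len(transfer_utrs({"d": two}, genome, ends, config)) == 1
        assert len(transfer_utrs({"d": three}, genome, ends, config)) == 0

    def test_seventy_percent_coverage_rejected(self, config):
        rng = np.random.default_rng(2)
        utr = _random_seq(rng, 100)
        # only 70% of the donor exists in the genome
        genome = _genome_with(rng, utr[:70], 2000)
        ends = pd.DataFrame({"name": ["g"], "end": [1990]})
        assert transfer_utrs({"d": utr}, genome, ends, config) == []

    def test_far_from_gene_end_rejected(self, config):
        utr, genome, _ = self._setup(seed=3)
        far = pd.DataFrame({"name": ["g"], "end": [200]})  # 1800 nt away
        assert transfer_utrs({"d": utr}, genome, far, config) == []

    def test_invariant_to_donor_order(self, config):
        rng = np.random.default_rng(4)
        u1, u2 = _random_seq(rng, 90), _random_seq(rng, 90)
        genome = _genome_with(rng, u1 + _random_seq(rng, 300) + u2, 1500, n=5000)
        ends = pd.DataFrame({"name": ["g1", "g2"], "end": [1450, 1950]})
        a = transfer_utrs({"x": u1, "y": u2}, genome, ends, config)
        b = transfer_utrs({"y": u2, "x": u1}, genome, ends, config)
        assert a == b
        assert [r.locus_start for r in a] == sorted(r.locus_start for r in a)


def oracle_sites(mature, utr_seq, min_score):
    """Position-by-position brute-force site scan, written independently."""
    L = len(mature)
    out = []
    for j in range(len(utr_seq) - L + 1):
        window = utr_seq[j:j + L]
        score, seed_wc, seed_gu = 0.0, 0, 0
        pos1_wc = False
        for k in range(1, L + 1):
            m, u = mature[k - 1], window[L - k]
            if RC[m] == u:
                score += 5
                if 2 <= k <= 8:
                    seed_wc += 1
                if k == 1:
                    pos1_wc = True
            elif (m, u) in (("G", "T"), ("T", "G")):
                score += 1
                if 2 <= k <= 8:
                    seed_gu += 1
            else:
                score -= 4
        if seed_wc == 7:
            cls = "8mer" if pos1_wc else "7mer"
        elif seed_wc == 6 and seed_gu == 1:
            cls = "7mer-wobble"
        else:
            continue
        if score >= min_score:
            out.append((j, cls, score))
    return out


class TestPredictTargets:
    def _utr(self, seq):
        return UTRRecord(gene="g", sequence=seq, source="unigene")

    def test_perfect_complement_is_8mer_max_score(self, config):
        rng = np.random.default_rng(5)
        mature = _random_seq(rng, 22)
        utr = self._utr(_random_seq(rng, 40) + revcomp(mature) + _random_seq(rng, 40))
        sites = predict_targets("mir", mature, utr, config)
        assert len(sites) >= 1
        best = max(sites, key=lambda s: s.score)
        assert best.seed_class == "8mer"
        assert best.score == 5.0 * 22
        assert best.paired_fraction == 1.0

    def test_seed_mismatch_kills_site(self, config):
        rng = np.random.default_rng(6)
        mature = _random_seq(rng, 22)
        site = list(revcomp(mature))
        # miRNA position 4 faces UTR base L-4; replace its partner with a
        # base that is neither Watson-Crick nor a G:U wobble
        m = mature[3]
        bad = next(b for b in "ACGT"
                   if b != RC[m] and (m, b) not in (("G", "T"), ("T", "G")))
        site[len(site) - 4] = bad
        broken = "".join(site)
        # ensure the seed is genuinely broken in the oracle's terms
        assert oracle_sites(mature, broken, 0) == []
        utr = self._utr(broken)
        assert predict_targets("mir", mature, utr, config) == []

    def test_wobble_site_classified(self, config):
        rng = np.random.default_rng(8)
        while True:
            mature = _random_seq(rng, 22)
            # wobble at miRNA position 5: G faces T, or T faces G
            if mature[4] in "GT":
                break
        site = list(revcomp(mature))
        site[len(site) - 5] = "T" if mature[4] == "G" else "G"
        utr = self._utr("".join(site))
        sites = predict_targets("mir", mature, utr, config)
        assert len(sites) == 1
        assert sites[0].seed_class == "7mer-wobble"
        assert sites[0].score == 5.0 * 21 + 1.0

    def test_mature_length_validated(self, config):
        with pytest.raises(ValueError):
            predict_targets("mir", "ACGT", self._utr("A" * 50), config)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed, config):
        rng = np.random.default_rng(seed)
        mature = _random_seq(rng, int(rng.integers(18, 27)))
        # half the pairs get a planted near-complement to exercise hits
        utr_seq = _random_seq(rng, int(rng.integers(60, 200)))
        if seed % 2:
            pos = int(rng.integers(0, len(utr_seq) - len(mature)))
            core = list(revcomp(mature))
            for p in rng.integers(8, len(core), size=rng.integers(0, 4)):
                core[p] = "ACGT"[rng.integers(4)]
            utr_seq = (utr_seq[:pos] + "".join(core)
                       + utr_seq[pos + len(core):])
        got = predict_targets("mir", mature, self._utr(utr_seq), config)
        expected = oracle_sites(mature, utr_seq, config.target_score_min)
        assert [(s.position, s.seed_class, s.score) for s in got] == expected

    def test_reported_seed_patterns_revalidate(self, config):
        rng = np.random.default_rng(123)
        mature = _random_seq(rng, 22)
        utr_seq = _random_seq(rng, 50) + revcomp(mature) + _random_seq(rng, 50)
        for site in predict_targets("mir", mature, self._utr(utr_seq), config):
            window = utr_seq[site.position:site.position + len(mature)]
            for k in range(2, 9):
                m, u = mature[k - 1], window[len(mature) - k]
                assert RC[m] == u or (m, u) in (("G", "T"), ("T", "G"))


class TestTallies:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["miRNA", "gene", "position",
                                           "seed_class", "score",
                                           "paired_fraction", "utr_source"])

    def test_hand_count(self):
        sites = self._sites([("m1", "g1", 0, "8mer", 110, 1.0, "unigene"),
                             ("m1", "g2", 0, "8mer", 110, 1.0, "unigene"),
                             ("m2", "g3", 0, "7mer", 100, 1.0, "unigene")])
        tally = tally_pathways(sites, {"g1": "P1", "g2": "P1", "g3": "P2"})
        t = tally.set_index("pathway")
        assert t.loc["P1", "target_genes"] == 2
        assert t.loc["P2", "target_genes"] == 1

    def test_empty_sites_empty_tally(self):
        assert tally_pathways(self._sites([]), {"g": "P"}).empty

    def test_gene_counted_once_per_pathway(self):
        sites = self._sites([("m1", "g1", 0, "8mer", 110, 1.0, "unigene"),
                             ("m2", "g1", 5, "7mer", 100, 1.0, "unigene")])
        tally = tally_pathways(sites, {"g1": "P1"}).set_index("pathway")
        assert tally.loc["P1", "target_genes"] == 1
        assert tally.loc["P1", "mirnas"] == 2

    def test_unmapped_genes_bucketed(self):
        sites = self._sites([("m1", "gX", 0, "8mer", 110, 1.0, "unigene")])
        tally = tally_pathways(sites, {}).set_index("pathway")
        assert tally.loc["unmapped", "target_genes"] == 1

    def test_both_counting_conventions(self):
        sites = self._sites([("m1", "g1", 0, "8mer", 110, 1.0, "unigene"),
                             ("m2", "g1", 3, "8mer", 110, 1.0, "unigene"),
                             ("m2", "g2", 0, "7mer", 100, 1.0, "unigene")])
        counts = target_counts(sites)
        assert counts == {"unique_genes": 2, "gene_mirna_pairs": 3}


class TestExpressionTrends:
    FPKM = pd.DataFrame({"y1": [10.0, 100.0, 5.0], "y2": [10.0, 120.0, 6.0],
                         "a1": [10.0, 10.0, 50.0], "a2": [10.0, 12.0, 60.0]},
                        index=["flat", "younghigh", "adulthigh"])
    GROUPS = {"y1": "young", "y2": "young", "a1": "adult", "a2": "adult"}

    def _run(self, genes):
        return compare_target_expression(self.FPKM, genes, self.GROUPS,
                                         ("young", "adult")).set_index("gene")

    def test_tied_gene(self):
        assert self._run(["flat"]).loc["flat", "trend"] == "tied"

    def test_directional_genes(self):
        out = self._run(["younghigh", "adulthigh"])
        assert out.loc["younghigh", "trend"] == "higher_in_young"
        assert out.loc["adulthigh", "trend"] == "higher_in_adult"

    def test_missing_gene_flagged(self):
        assert self._run(["nope"]).loc["nope", "trend"] == "missing"

    def test_planted_directions_recovered(self):
        rng = np.random.default_rng(77)
        genes, rows, expected = [], [], {}
        for i in range(30):
            direction = ["higher_in_young", "higher_in_adult", "tied"][i % 3]
            base = float(rng.uniform(5, 50))
            if direction == "higher_in_young":
                rows.append([base * 2, base * 2.1, base, base * 1.05])
            elif direction == "higher_in_adult":
                rows.append([base, base * 1.05, base * 2, base * 2.1])
            else:
                rows.append([base, base * 1.02, base * 0.99, base])
            genes.append(f"g{i}")
            expected[f"g{i}"] = direction
        fpkm = pd.DataFrame(rows, index=genes, columns=["y1", "y2", "a1", "a2"])
        out = compare_target_expression(fpkm, genes, self.GROUPS,
                                        ("young", "adult")).set_index("gene")
        for gene, want in expected.items():
            assert out.loc[gene, "trend"] == want


def test_unigene_utrs_verbatim():
    records = unigene_utrs({"u2": "acgt" * 10, "u1": "GGCC" * 10})
    assert [r.gene for r in records] == ["u1", "u2"]
    assert records[1].sequence == "ACGT" * 10
    assert all(r.source == "unigene" for r in records)


def test_predict_all_combines_sources(config):
    rng = np.random.default_rng(9)
    mature = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 22)])
    utrs = [UTRRecord(gene="g1", sequence=revcomp(mature), source="unigene"),
            UTRRecord(gene="g2", sequence="A" * 60, source="transferred")]
    sites = predict_all({"mir-a": mature}, utrs, config)
    assert set(sites["gene"]) == {"g1"}
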