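"""Synthetic-data generator: distributional and ground-truth guarantees."""

import numpy as np
import pandas as pd
import pytest

from ribote.counting import CountTable, assign_asite
from ribote.simulate import (
    FragmentProfile,
    SimDesign,
    make_transcriptome,
    read_fragments,
    simulate_counts,
    simulate_fragments,
    write_fragments,
)
from ribote.uorf import find_start_sites

STOPS = {"TAA", "TAG", "TGA"}


class TestMakeTranscriptome:
    def test_empty(self):
        txs, planted = make_transcriptome(0, seed=1)
        assert txs == {} and planted == {}

    def test_cds_structure(self, toy_transcriptome):
        txs, _ = toy_transcriptome
        for t in txs.values():
            cds = t.cds
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in STOPS
            internal = {cds[i : i + 3] for i in range(0, len(cds) - 3, 3)}
            assert not (internal & STOPS)

    def test_no_uaugs_when_expected_zero(self):
        txs, planted = make_transcriptome(
            20, uorf_params={"expected_uaugs": 0}, seed=5
        )
        for g, t in txs.items():
            assert "ATG" not in t.utr5
            assert planted[g] == []

    def test_cds_too_short_rejected(self):
        with pytest.raises(ValueError, match="CDS"):
            make_transcriptome(1, length_params={"cds": (3, 9)}, seed=0)

    def test_planted_uaugs_recovered_by_scanner(self):
        """Cross-module ground truth: the uORF scanner finds exactly the
        planted uAUG positions in every generated 5'UTR."""
        txs, planted = make_transcriptome(100, seed=1)
        for g, t in txs.items():
            found = [
                s.position for s in find_start_sites(t.utr5, t.cds) if s.canonical
            ]
            assert found == planted[g]


class TestSimulateCounts:
    @staticmethod
    def design(n_genes=3, mean=50.0, te=0.0, alpha=0.0, reps=3, seed=0, **kw):
        return SimDesign(
            n_genes=n_genes,
            mean_expression=np.full(n_genes, mean),
            log2_te=np.full(n_genes, te),
            dispersion=np.full(n_genes, alpha),
            n_replicates=reps,
            seed=seed,
            **kw,
        )

    def test_zero_dispersion_is_poisson(self):
        # alpha=0, TE=0, s_j=1: counts are Poisson(mean); the sample mean
        # over 10,000 draws per gene must sit within 3 SE of the mean
        mean = 80.0
        d = self.design(n_genes=3, mean=mean, reps=5000, seed=2)
        table = simulate_counts(d)
        draws = table.counts.to_numpy()
        assert draws.shape == (3, 10000)
        se = np.sqrt(mean / draws.shape[1])
        assert np.all(np.abs(draws.mean(axis=1) - mean) < 3 * se)
        # Poisson: variance approximately equals the mean
        assert np.all(np.abs(draws.var(axis=1) / mean - 1) < 0.1)

    def test_te_doubles_ribo_mean(self):
        d = self.design(n_genes=4, mean=100.0, te=1.0, alpha=0.0, reps=2000, seed=3)
        table = simulate_counts(d)
        ribo = table.design["library_type"] == "Ribo"
        ratio = (
            table.counts.loc[:, ribo.to_numpy()].mean(axis=1)
            / table.counts.loc[:, (~ribo).to_numpy()].mean(axis=1)
        )
        assert np.allclose(ratio, 2.0, atol=0.1)

    def test_determinism(self):
        d1 = self.design(seed=11, alpha=0.1)
        d2 = self.design(seed=11, alpha=0.1)
        t1, t2 = simulate_counts(d1), simulate_counts(d2)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        t3 = simulate_counts(self.design(seed=12, alpha=0.1))
        assert not t1.counts.equals(t3.counts)

    def test_size_factor_scales_mean(self):
        sf = np.array([1.0, 2.0] * 3)
        d = self.design(n_genes=2, mean=200.0, reps=3, seed=4, size_factors=sf)
        table = simulate_counts(d)
        doubled = table.counts.loc[:, sf == 2.0].mean(axis=1)
        single = table.counts.loc[:, sf == 1.0].mean(axis=1)
        assert np.all(doubled > single)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            self.design(mean=-1.0)
        with pytest.raises(ValueError):
            self.design(alpha=-0.1)
        with pytest.raises(ValueError):
            SimDesign(
                n_genes=2,
                mean_expression=[10.0, 10.0],
                log2_te=[0.0],
                dispersion=[0.0, 0.0],
            )


class TestSimulateFragments:
    @staticmethod
    def single_lib_table(genes, n, library="Ribo"):
        design = pd.DataFrame(
            {"library_type": [library], "replicate": ["rep1"], "tissue": ["mesoderm"]},
            index=pd.Index([f"mesoderm_{library}_rep1"], name="library_id"),
        )
        counts = pd.DataFrame({design.index[0]: n}, index=list(genes))
        return CountTable(counts=counts, design=design)

    def test_counts_conservation(self, toy_transcriptome):
        txs, _ = toy_transcriptome
        rng = np.random.default_rng(0)
        design = pd.DataFrame(
            {
                "library_type": ["Ribo", "RNA"],
                "replicate": ["rep1", "rep1"],
                "tissue": ["mesoderm"] * 2,
            },
            index=pd.Index(["mesoderm_Ribo_rep1", "mesoderm_RNA_rep1"], name="library_id"),
        )
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(len(txs), 2)),
            index=list(txs),
            columns=design.index,
        )
        table = CountTable(counts=counts, design=design)
        frags = simulate_fragments(txs, table, seed=9)
        emitted = frags.groupby(
            [frags["transcript_id"], frags["library"]]
        ).size()
        for lib_id in counts.columns:
            lib = design.loc[lib_id, "library_type"]
            for gene in counts.index:
                expect = counts.loc[gene, lib_id]
                got = emitted.get((gene, lib), 0)
                assert got == expect

    def test_degenerate_frame_all_cds_frame0(self, toy_transcriptome):
        txs, _ = toy_transcriptome
        profile = FragmentProfile(frame_bias=(1.0, 0.0, 0.0), cds_fraction=1.0)
        table = self.single_lib_table(txs, 50)
        frags = simulate_fragments(txs, table, profile=profile, seed=1)
        assigned, dropped = assign_asite(frags, txs)
        assert dropped == 0
        for _, row in assigned.iterrows():
            t = txs[row["transcript_id"]]
            assert t.cds_start <= row["asite"] < t.cds_end
            assert (row["asite"] - t.cds_start) % 3 == 0

    def test_fragments_stay_in_bounds(self, toy_transcriptome):
        txs, _ = toy_transcriptome
        table = self.single_lib_table(txs, 200)
        frags = simulate_fragments(txs, table, seed=6)
        ends = frags["pos5"] + frags["length"]
        lengths = frags["transcript_id"].map({g: t.length for g, t in txs.items()})
        assert (frags["pos5"] >= 0).all()
        assert (ends <= lengths).all()

    def test_rna_positions_roughly_uniform(self):
        # equal-length regions: RNA A-site region fractions near (1/3, 1/3, 1/3)
        from ribote import qc
        from ribote.transcripts import TranscriptModel

        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=900))
        seq = seq[:300] + "ATG" + seq[303:897] + "TAA" + seq[900:]
        tx = TranscriptModel("g0", seq, 300, 300, 300)
        table = self.single_lib_table(["g0"], 30000, library="RNA")
        frags = simulate_fragments({"g0": tx}, table, seed=3)
        regions, _ = qc.region_distribution(frags, {"g0": tx})
        for frac in regions.values():
            assert abs(frac - 1 / 3) < 0.04

    def test_fragment_tsv_round_trip(self, toy_transcriptome, tmp_path):
        txs, _ = toy_transcriptome
        table = self.single_lib_table(txs, 5)
        frags = simulate_fragments(txs, table, seed=4)
        path = tmp_path / "frags.tsv"
        write_fragments(frags, path)
        back = read_fragments(path)
        pd.testing.assert_frame_equal(frags, back)
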