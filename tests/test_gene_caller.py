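import itertools

import numpy as np
import pytest

from zgene import gene_caller, orf_model, sequence_io, synthetic, zcurve
from zgene import classifier as clf
from zgene.gene_caller import CallerConfig, resolve_overlaps
from zgene.orf_model import OrfCandidate
from zgene.sequence_io import GenomeSequence


def make_orf(start, end, strand="+", contig="c"):
    return OrfCandidate(
        contig_id=contig, strand=strand, start=start, end=end, frame=start % 3,
        seq="A" * (end - start),
    )


class TestResolveOverlaps:
    def test_nested_dominance(self):
        a, b = make_orf(0, 300), make_orf(30, 240)
        kept = resolve_overlaps([(a, 2.0), (b, 1.0)], max_overlap_nt=30)
        assert [o for o, _ in kept] == [a]

    def test_small_overlap_keeps_both(self):
        a, b = make_orf(0, 120), make_orf(110, 240)
        kept = resolve_overlaps([(a, 2.0), (b, 1.0)], max_overlap_nt=30)
        assert len(kept) == 2

    def test_opposite_strand_overlap_also_capped(self):
        a, b = make_orf(0, 300, "+"), make_orf(100, 250, "-")
        kept = resolve_overlaps([(a, 2.0), (b, 1.9)], max_overlap_nt=30)
        assert len(kept) == 1

    def test_different_contigs_never_conflict(self):
        a, b = make_orf(0, 300, contig="c1"), make_orf(0, 300, contig="c2")
        assert len(resolve_overlaps([(a, 1.0), (b, 1.0)], 30)) == 2

    @staticmethod
    def exhaustive_best(scored, cap):
        """Brute-force oracle: subset maximizing total score under the
        pairwise overlap cap."""
        n = len(scored)
        conflict = np.zeros((n, n), dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            oi, oj = scored[i][0], scored[j][0]
            ov = clf._interval_overlap(oi.start, oi.end, oj.start, oj.end)
            conflict[i, j] = conflict[j, i] = (
                oi.contig_id == oj.contig_id and ov > cap
            )
        best = 0.0
        for mask in range(1 << n):
            members = [i for i in range(n) if mask >> i & 1]
            if any(conflict[i, j] for i, j in itertools.combinations(members, 2)):
                continue
            best = max(best, sum(scored[i][1] for i in members))
        return best

    @pytest.mark.parametrize("seed", range(6))
    def test_selection_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        scored = []
        for _ in range(n):
            s = int(rng.integers(0, 900))
            L = int(rng.integers(90, 400)) // 3 * 3
            scored.append((make_orf(s, s + L), float(rng.uniform(0.1, 3.0))))
        total = sum(s for _, s in resolve_overlaps(scored, 30))
        assert total == pytest.approx(self.exhaustive_best(scored, 30))


class TestRelocateStart:
    def test_single_candidate_unchanged(self, pipeline_main):
        g = pipeline_main["synth"]
        model = pipeline_main["model"]
        config = pipeline_main["config"]
        singles = [o for o in pipeline_main["orfs"] if len(o.alt_start_offsets) == 1]
        orf = singles[0]
        pred = gene_caller._orf_to_prediction(orf, 1.0, len(g.genome))
        out = gene_caller.relocate_start(pred, orf, g.genome, model, config)
        assert out == pred and not out.start_relocated

    def test_sd_motif_selects_true_start(self, pipeline_main):
        """A spurious in-frame upstream ATG without a ribosome-binding site
        must lose to the true start with a perfect AGGAGG 8 nt upstream."""
        g = pipeline_main["synth"]
        model = pipeline_main["model"]
        config = pipeline_main["config"]
        rng = np.random.default_rng(0)
        table = g.codon_table
        codons = np.array(synthetic.SENSE_CODONS)
        probs = np.array([table[c] for c in synthetic.SENSE_CODONS])
        gene = "ATG" + "".join(codons[rng.choice(61, size=120, p=probs)]) + "TAA"
        # upstream decoy: in-frame ATG + non-stop junk, no SD motif
        decoy = "ATG" + "CACCAC" * 4
        # 18 nt, in-frame codons CCC CAG GAG GCC CCC CCC (no stops);
        # AGGAGG ends 8 nt before the gene start
        upstream = "CCCC" + "AGGAGG" + "CC" + "CCCCCC"
        prefix = "C" * 60
        seq = prefix + decoy + upstream + gene + "C" * 60
        genome = GenomeSequence(id="t", seq=seq)
        orfs = [
            o for o in orf_model.extract_orfs(genome)
            if o.strand == "+" and o.seq.endswith(gene[-30:])
        ]
        assert len(orfs) == 1
        orf = orfs[0]
        assert len(orf.alt_start_offsets) > 1
        true_start = seq.index(gene) + 1
        pred = gene_caller._orf_to_prediction(orf, 1.0, len(seq))
        out = gene_caller.relocate_start(pred, orf, genome, model, config)
        assert out.start == true_start
        assert out.start_relocated

    def test_stop_coordinate_never_moves(self, pipeline_main):
        g = pipeline_main["synth"]
        model = pipeline_main["model"]
        config = pipeline_main["config"]
        multi = [o for o in pipeline_main["orfs"] if len(o.alt_start_offsets) > 1]
        for orf in multi[:300]:
            pred = gene_caller._orf_to_prediction(orf, 1.0, len(g.genome))
            out = gene_caller.relocate_start(pred, orf, g.genome, model, config)
            assert out.stop_coord == pred.stop_coord
            assert out.strand == pred.strand


class TestPredictGenes:
    def test_recovery_on_reference_conditions(self, pipeline_main):
        from zgene import evaluation

        g = pipeline_main["synth"]
        rep = evaluation.coding_report(pipeline_main["predictions"], g.truth)
        assert rep.sn >= 0.90
        assert rep.ppv >= 0.90

    def test_prediction_invariants(self, pipeline_main):
        g = pipeline_main["synth"]
        seq = g.genome.seq
        stops = {"TAA", "TAG", "TGA"}
        for p in pipeline_main["predictions"]:
            assert p.length % 3 == 0
            assert p.coding_score > pipeline_main["config"].threshold
            dna = sequence_io.gene_dna(p, g.genome)
            assert dna[-3:] in stops

    def test_sorted_by_position(self, pipeline_main):
        preds = pipeline_main["predictions"]
        keys = [(p.contig_id, p.start) for p in preds]
        assert keys == sorted(keys)

    def test_threshold_monotonicity(self, pipeline_main):
        g = pipeline_main["synth"]
        model = pipeline_main["model"]
        counts = []
        for thr in (0.0, 0.5, 1.5, 3.0):
            cfg = CallerConfig(seed=1, threshold=thr, relocate_starts=False)
            preds = gene_caller.predict_genes([g.genome], cfg, model=model)
            counts.append(len(preds))
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_output(self, tmp_path):
        spec = synthetic.SyntheticGenomeSpec(length=120_000, n_genes=90, seed=17)
        g = synthetic.generate_genome(spec)
        paths = []
        for run in (1, 2):
            preds = gene_caller.predict_genes([g.genome], CallerConfig(seed=17))
            out = sequence_io.write_outputs(
                preds, [g.genome], tmp_path / f"run{run}", options=["coords"]
            )
            paths.append(out["coords"])
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_null_genome_with_pretrained_model(self, pipeline_main):
        """A pretrained model applied to pure random sequence should call
        almost nothing."""
        rng = np.random.default_rng(123)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        genome = GenomeSequence(id="null", seq=seq)
        cfg = CallerConfig(seed=1, relocate_starts=False)
        preds = gene_caller.predict_genes([genome], cfg, model=pipeline_main["model"])
        assert len(preds) <= 5

    def test_no_orfs_gives_empty_output(self):
        genome = GenomeSequence(id="e", seq="ACGT" * 30)
        cfg = CallerConfig(seed=0, min_orf_len=300)
        assert gene_caller.predict_genes([genome], cfg) == []
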