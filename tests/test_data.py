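import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from ibag.data import (
    GenomicsDataset,
    OutcomeSpec,
    ProbeGeneMap,
    load_dataset,
    load_matrix,
    load_outcome,
    map_probes_to_promoters,
    read_gff3_genes,
    validate_dataset,
)
from ibag.simulation import SimConfig, simulate_dataset, write_dataset

from oracles import brute_force_promoter_map


def _write_matrix(path, frame):
    frame.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.17g")


class TestLoadMatrix:
    def test_roundtrip_preserves_values_exactly(self, tmp_path, rng):
        frame = pd.DataFrame(
            rng.standard_normal((10, 5)),
            index=[f"s{i}" for i in range(10)],
            columns=[f"f{j}" for j in range(5)],
        )
        _write_matrix(tmp_path / "m.tsv", frame)
        back = load_matrix(tmp_path / "m.tsv")
        assert list(back.index) == list(frame.index)
        assert list(back.columns) == list(frame.columns)
        np.testing.assert_array_equal(back.to_numpy(), frame.to_numpy())

    def test_non_numeric_cell_is_named(self, tmp_path):
        (tmp_path / "m.tsv").write_text("sample_id\tg1\tg2\ns1\t0.5\tNA\ns2\t1\t2\n")
        with pytest.raises(ValueError, match=r"s1.*g2|g2.*s1"):
            load_matrix(tmp_path / "m.tsv")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("sample_id\tg1\ns1\t0.5\ns1\t1.0\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            load_matrix(tmp_path / "m.tsv")


class TestLoadOutcome:
    def test_survival_outcome(self, tmp_path):
        (tmp_path / "o.tsv").write_text(
            "sample_id\tvalue\tevent\ns1\t4.2\t1\ns2\t1.1\t0\ns3\t9.9\t1\n"
        )
        out = load_outcome(tmp_path / "o.tsv", "survival")
        assert out.family == "survival" and len(out) == 3
        np.testing.assert_array_equal(out.event, [1.0, 0.0, 1.0])

    def test_continuous_roundtrip_exact(self, tmp_path):
        values = [0.125, -3.5, 2.25, 100.0, -0.0625]  # exactly representable
        lines = ["sample_id\tvalue"] + [f"s{i}\t{v}" for i, v in enumerate(values)]
        (tmp_path / "o.tsv").write_text("\n".join(lines) + "\n")
        out = load_outcome(tmp_path / "o.tsv", "continuous")
        np.testing.assert_array_equal(out.values, values)

    @pytest.mark.parametrize(
        "body,family,msg",
        [
            ("s1\t2\n", "binary", "binary"),
            ("s1\t-1.0\t1\n", "survival", "positive"),
            ("s1\t1.0\t2\n", "survival", "event"),
            ("s1\t1.0\n", "survival", "event"),
        ],
    )
    def test_invalid_outcomes_rejected(self, tmp_path, body, family, msg):
        header = "sample_id\tvalue\tevent\n" if body.count("\t") == 2 else "sample_id\tvalue\n"
        (tmp_path / "o.tsv").write_text(header + body)
        with pytest.raises(ValueError, match=msg):
            load_outcome(tmp_path / "o.tsv", family)


class TestPromoterMapping:
    def _genes(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [10000], "end": [12000],
             "name": ["gA"], "strand": ["+"]}
        )

    def _probe(self, pos):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [pos], "end": [pos + 1], "name": ["p1"]}
        )

    def test_interior_probe_maps(self):
        pm = map_probes_to_promoters(self._probe(10000 - 100), self._genes(), (1500, 500))
        assert pm.entries == (("p1", "gA"),)

    def test_halfopen_boundaries(self):
        # left edge inclusive, right edge exclusive
        assert map_probes_to_promoters(self._probe(10000 - 1500), self._genes()).entries
        assert not map_probes_to_promoters(self._probe(10000 + 500), self._genes()).entries

    def test_minus_strand_orientation(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10000], "end": [12000],
             "name": ["gB"], "strand": ["-"]}
        )
        # TSS is the last transcribed base (11999); upstream extends rightward
        assert map_probes_to_promoters(self._probe(11999 + 1500), genes).entries
        assert not map_probes_to_promoters(self._probe(11999 - 500), genes).entries
        assert map_probes_to_promoters(self._probe(11999 - 499), genes).entries

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            map_probes_to_promoters(self._probe(0), self._genes(), (-1, 500))

    def test_missing_strand_rejected(self):
        genes = self._genes().drop(columns="strand")
        with pytest.raises(ValueError, match="strand"):
            map_probes_to_promoters(self._probe(0), genes)

    def test_matches_bruteforce_oracle_on_random_layouts(self, rng):
        for _ in range(100):
            n_p, n_g = rng.integers(1, 15), rng.integers(1, 8)
            chroms = ["chr1", "chr2"]
            probes = []
            for i in range(n_p):
                start = int(rng.integers(0, 50000))
                probes.append((chroms[rng.integers(2)], start, start + int(rng.integers(1, 100)), f"p{i}"))
            genes = []
            for i in range(n_g):
                start = int(rng.integers(0, 50000))
                genes.append(
                    (chroms[rng.integers(2)], start, start + int(rng.integers(500, 5000)),
                     f"g{i}", "+" if rng.random() < 0.5 else "-")
                )
            up, down = int(rng.integers(0, 3000)), int(rng.integers(0, 2000))
            got = map_probes_to_promoters(
                pd.DataFrame(probes, columns=["chrom", "start", "end", "name"]),
                pd.DataFrame(genes, columns=["chrom", "start", "end", "name", "strand"]),
                (up, down),
            )
            expected = brute_force_promoter_map(probes, genes, up, down)
            assert sorted(got.entries) == sorted(expected)

    def test_gff3_gene_extraction(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t10001\t12000\t.\t+\t.\tID=gA;Name=alpha\n"
            "chr1\tsrc\texon\t10001\t10500\t.\t+\t.\tID=gA.e1\n"
            "chr2\tsrc\tgene\t500\t900\t.\t-\t.\tgene_id=gB\n"
        )
        (tmp_path / "genes.gff3").write_text(gff)
        genes = read_gff3_genes(tmp_path / "genes.gff3")
        assert list(genes["name"]) == ["gA", "gB"]
        assert genes.loc[0, "start"] == 10000  # converted to 0-based
        assert genes.loc[1, "strand"] == "-"


def _manual_dataset():
    ids = ["A", "B", "C"]
    expr = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], index=ids, columns=["g1", "g2"])
    meth = pd.DataFrame([[0.1], [0.5], [0.9]], index=ids, columns=["p1"])
    outcome = OutcomeSpec("continuous", tuple(ids), np.array([1.0, 2.0, 3.0]))
    return GenomicsDataset(
        sample_ids=tuple(ids),
        expression=expr,
        methylation=meth,
        covariates=pd.DataFrame(index=ids),
        outcome=outcome,
        probe_map=ProbeGeneMap(entries=(("p1", "g1"),)),
    )


class TestValidateDataset:
    def test_sample_intersection(self):
        ds = _manual_dataset()
        ds = replace(ds, expression=ds.expression.loc[["B", "C"]].copy())
        ds = replace(ds, expression=pd.concat(
            [ds.expression, pd.DataFrame([[7.0, 8.0]], index=["D"], columns=["g1", "g2"])]
        ))
        validated = validate_dataset(ds)
        assert validated.sample_ids == ("B", "C")
        assert len(validated.outcome) == 2

    def test_methylation_out_of_range_rejected(self):
        ds = _manual_dataset()
        ds.methylation.loc["A", "p1"] = 1.2
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            validate_dataset(ds)

    def test_permutation_invariance(self):
        ds = _manual_dataset()
        shuffled = replace(
            ds,
            expression=ds.expression.loc[["C", "A", "B"]],
            methylation=ds.methylation.loc[["B", "C", "A"]],
        )
        v1, v2 = validate_dataset(ds), validate_dataset(shuffled)
        assert v1.sample_ids == v2.sample_ids
        pd.testing.assert_frame_equal(v1.expression, v2.expression)
        pd.testing.assert_frame_equal(v1.methylation, v2.methylation)

    def test_idempotent(self):
        v1 = validate_dataset(_manual_dataset())
        v2 = validate_dataset(v1)
        assert v1.sample_ids == v2.sample_ids
        pd.testing.assert_frame_equal(v1.expression, v2.expression)
        np.testing.assert_array_equal(v1.outcome.values, v2.outcome.values)

    def test_empty_intersection_rejected(self):
        ds = _manual_dataset()
        ds = replace(ds, expression=ds.expression.set_axis(["X", "Y", "Z"], axis=0))
        with pytest.raises(ValueError, match="shared"):
            validate_dataset(ds)

    def test_unknown_probe_reference_rejected(self):
        ds = replace(_manual_dataset(), probe_map=ProbeGeneMap(entries=(("nope", "g1"),)))
        with pytest.raises(ValueError, match="unknown methylation"):
            validate_dataset(ds)


def test_dataset_directory_roundtrip(tmp_path):
    cfg = SimConfig(n=20, k=8, j=4, rho=-0.5, group_size=1, seed=3)
    ds, truth = simulate_dataset(cfg, 0)
    write_dataset(ds, truth, tmp_path)
    back = load_dataset(tmp_path, "continuous")
    assert back.sample_ids == ds.sample_ids
    np.testing.assert_allclose(back.expression.to_numpy(), ds.expression.to_numpy(), rtol=0, atol=1e-12)
    np.testing.assert_allclose(back.methylation.to_numpy(), ds.methylation.to_numpy(), rtol=0, atol=1e-12)
    assert back.probe_map.entries == ds.probe_map.entries
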