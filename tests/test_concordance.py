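import numpy as np
import pandas as pd
import pytest

import amplicord as ac
from amplicord.insilico_pcr import SHORT_READ_PRIMERS
from amplicord.io_formats import lineage_from_string


def _table(taxa_counts, samples, lineage_strings):
    taxa = list(taxa_counts)
    return ac.OTUTable(
        taxa=taxa,
        samples=samples,
        counts=np.array([taxa_counts[t] for t in taxa]),
        lineages={t: lineage_from_string(t, lineage_strings[t]) for t in taxa},
    )


def test_venn_counts_arithmetic_identity():
    venn = ac.VennCounts(n_total=1028, n_concordant=770, n_discordant=258)
    assert round(venn.pct_discordant, 2) == 25.10
    with pytest.raises(ValueError):
        ac.VennCounts(10, 5, 4)


def test_recreate_reference_reads(records20, index20):
    ids = [r.id for r in records20[:10]]
    out = ac.recreate_reference_reads(index20, ids)
    assert [r.id for r in out] == ids
    assert all(o.seq == r.seq for o, r in zip(out, records20[:10]))
    # duplicates collapse to one record
    assert len(ac.recreate_reference_reads(index20, ids + ids[:3])) == 10
    with pytest.raises(ValueError, match="NOPE"):
        ac.recreate_reference_reads(index20, ids + ["NOPE"])


def test_bias_audit_no_confusable_groups_fully_concordant():
    db = ac.build_reference_db(10, 0, seed=5)
    report = ac.bias_audit(
        ac.db_records(db), [t.accession for t in db], SHORT_READ_PRIMERS
    )
    for venn in report.venn.values():
        assert venn.n_discordant == 0
        assert venn.pct_discordant == 0.0
    assert report.n_unique_after_clustering == 10


def test_bias_audit_confusable_pairs_counted_once_each(db20, index20):
    """One member of each identical-region pair loses the tie-break."""
    report = ac.bias_audit(index20, [t.accession for t in db20], SHORT_READ_PRIMERS)
    assert report.venn["full_length_best_hit"].n_discordant == 0
    assert report.venn["region_best_hit"].n_discordant == 4
    assert report.venn["region_best_hit"].pct_discordant == pytest.approx(20.0)
    assert report.venn["region_cluster_closed_ref"].n_discordant == 4
    # both region paths agree with each other on every sequence
    assert report.cross_path.n_discordant == 0
    # the 4 identical pairs collapse 20 unique regions to 16 clusters
    assert report.n_input_sequences == 20
    assert report.n_unique_after_clustering == 16
    # the losing member is always the lexicographically larger accession
    for g in range(4):
        keep, lose = db20[2 * g].accession, db20[2 * g + 1].accession
        assert report.assignments["region_best_hit"][lose] == keep
        assert report.assignments["region_best_hit"][keep] == keep


def test_bias_audit_discordance_monotone_in_confusable_groups():
    discordant = []
    for n_groups in (0, 2, 4):
        db = ac.build_reference_db(16, n_groups, 2, seed=9)
        report = ac.bias_audit(
            ac.db_records(db), [t.accession for t in db], SHORT_READ_PRIMERS
        )
        discordant.append(report.venn["region_best_hit"].n_discordant)
    assert discordant == sorted(discordant)
    assert discordant[0] == 0 and discordant[-1] == 4


def test_merge_platform_tables_rare_filter():
    lineages = {f"T{i}": "Bacteria;P;C;O;F;G;S" + str(i) for i in range(4)}
    a = _table({"T0": [5, 3], "T1": [3, 2], "T2": [9, 9]}, ["s1", "s2"], lineages)
    b = _table({"T2": [4, 4], "T3": [2, 8]}, ["s1", "s2"], lineages)
    merged = ac.merge_platform_tables(a, b, min_count=4, suffixes=("_i", "_m"))
    frame = merged.to_frame()
    # cell filter: [5,3] -> [5,0]; [3,2] -> dropped entirely
    assert list(frame.loc["T0"]) == [5, 0, 0, 0]
    assert "T1" not in merged.taxa
    assert list(frame.loc["T3"]) == [0, 0, 0, 8]
    assert merged.samples == ["s1_i", "s2_i", "s1_m", "s2_m"]

    with pytest.raises(ValueError, match="duplicate"):
        ac.merge_platform_tables(a, b, suffixes=("_x", "_x"))


def test_merge_platform_tables_row_mode():
    lineages = {"T0": "Bacteria;P;C;O;F;G;S0", "T1": "Bacteria;P;C;O;F;G;S1"}
    a = _table({"T0": [2, 1], "T1": [3, 3]}, ["s1", "s2"], lineages)
    b = _table({"T0": [1, 1]}, ["s1", "s2"], lineages)
    merged = ac.merge_platform_tables(a, b, min_count=4, filter_mode="row")
    # row sums: T0 in a = 3 < 4 dropped, T1 = 6 kept; b's T0 = 2 dropped
    assert merged.taxa == ["T1"]


def test_merge_disjoint_taxa_sets():
    lineages = {f"T{i}": "Bacteria;P;C;O;F;G;S" + str(i) for i in range(4)}
    a = _table({"T0": [10], "T1": [10]}, ["s1"], lineages)
    b = _table({"T2": [10], "T3": [10]}, ["s1"], lineages)
    merged = ac.merge_platform_tables(a, b, min_count=4)
    assert len(merged.taxa) == 4


def test_aggregate_rank_grouping_and_conservation():
    lineages = {
        "X1": "Bacteria;P1;C1;O1;F1;G1;S1",
        "X2": "Bacteria;P1;C1;O1;F1;G1;S2",
        "X3": "Bacteria;P2;C2;O2;F2;G2;S3",
    }
    table = _table({"X1": [3], "X2": [1], "X3": [4]}, ["s"], lineages)
    genus = ac.aggregate_rank(table, "genus").abundance
    assert genus.loc["G1", "s"] == pytest.approx(0.5)
    species = ac.aggregate_rank(table, "species").abundance
    assert species.loc["S1", "s"] == pytest.approx(3 / 8)
    for rank in ac.RANKS:
        agg = ac.aggregate_rank(table, rank).abundance
        assert agg["s"].sum() == pytest.approx(1.0)

    unassigned = _table(
        {"X1": [3], "X2": [5]},
        ["s"],
        {"X1": "Bacteria", "X2": "Bacteria"},
    )
    genus_u = ac.aggregate_rank(unassigned, "genus").abundance
    assert list(genus_u.index) == [ac.UNASSIGNED]
    assert genus_u.loc[ac.UNASSIGNED, "s"] == pytest.approx(1.0)

    with pytest.raises(ValueError):
        ac.aggregate_rank(table, "kingdom")


def test_spearman_rho_values():
    assert ac.spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
    assert ac.spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
    # hand computation with average ranks: rx=[1,2.5,2.5,4], ry=[1,3,2,4]
    # -> Pearson of ranks = 4.5/sqrt(4.5*5) = 3/sqrt(10)
    assert ac.spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(3 / np.sqrt(10))
    assert np.isnan(ac.spearman_rho([1, 1, 1], [1, 2, 3]))
    with pytest.raises(ValueError):
        ac.spearman_rho([1, 2], [1, 2])


def test_cross_platform_correlation_identical_tables():
    lineages = {
        "X1": "Bacteria;P1;C1;O1;F1;G1;S1",
        "X2": "Bacteria;P2;C2;O2;F2;G2;S2",
        "X3": "Bacteria;P3;C3;O3;F3;G3;S3",
    }
    a = _table({"X1": [10], "X2": [5], "X3": [1]}, ["s1"], lineages)
    b = _table({"X1": [20], "X2": [10], "X3": [2]}, ["s1"], lineages)
    merged = ac.merge_platform_tables(a, b, min_count=0)
    rho = ac.cross_platform_correlation(merged, ["s1_illumina"], ["s1_minion"])
    for rank, value in rho.items():
        assert value == pytest.approx(1.0), rank


def test_cross_platform_correlation_independent_tables_near_zero():
    rng = np.random.default_rng(7)
    rhos = []
    lineages = {f"X{i}": f"Bacteria;P{i};C{i};O{i};F{i};G{i};S{i}" for i in range(12)}
    for _ in range(100):
        a = _table(
            {t: [int(v)] for t, v in zip(lineages, rng.integers(1, 200, 12))},
            ["s1"],
            lineages,
        )
        b = _table(
            {t: [int(v)] for t, v in zip(lineages, rng.integers(1, 200, 12))},
            ["s1"],
            lineages,
        )
        merged = ac.merge_platform_tables(a, b, min_count=0)
        rhos.append(
            ac.cross_platform_correlation(
                merged, ["s1_illumina"], ["s1_minion"], ranks=("species",)
            )["species"]
        )
    assert abs(np.mean(rhos)) < 0.1


def test_abundance_change_heatmap_threshold_and_identity():
    lineages = {
        "X1": "Bacteria;P1;C1;O1;F1;G1;S1",
        "X2": "Bacteria;P2;C2;O2;F2;G2;S2",
        "X3": "Bacteria;P3;C3;O3;F3;G3;S3",
    }
    # X3 sits at 0.4% in both tables -> excluded at the 0.5% threshold
    a = _table({"X1": [600], "X2": [396], "X3": [4]}, ["s"], lineages)
    heat = ac.abundance_change_heatmap({"t1": a, "t2": a}, ranks=("species",))
    matrix = heat["species"]
    assert "S3" not in matrix.index
    assert (matrix["t1"] - matrix["t2"]).abs().max() == 0.0
    assert matrix.loc["S1", "t1"] == pytest.approx(60.0)


def test_abundance_change_heatmap_confusable_collapse(db20, lineages20):
    """When a pair collapses, the winner's percentage is the pair's sum."""
    a0, a1 = db20[0].accession, db20[1].accession
    other = db20[10].accession
    original = ac.OTUTable(
        taxa=[a0, a1, other],
        samples=["s"],
        counts=np.array([[30], [30], [40]]),
        lineages={t: lineages20[t] for t in (a0, a1, other)},
    )
    collapsed = ac.OTUTable(
        taxa=[a0, other],
        samples=["s"],
        counts=np.array([[60], [40]]),
        lineages={t: lineages20[t] for t in (a0, other)},
    )
    heat = ac.abundance_change_heatmap(
        {"ORIGINAL": original, "cluster": collapsed}, ranks=("species",)
    )["species"]
    s0 = lineages20[a0].at("species")
    s1 = lineages20[a1].at("species")
    assert heat.loc[s0, "cluster"] == pytest.approx(
        heat.loc[s0, "ORIGINAL"] + heat.loc[s1, "ORIGINAL"]
    )
    assert heat.loc[s1, "cluster"] == 0.0


def test_unique_taxa_by_similarity_confusable_pair(db20, index20, even4_profile):
    """The pair member that loses every long-read tie-break shows up as
    unique to the platform that kept a representative for it."""
    keep, lose = db20[0], db20[1]
    region = {
        t.accession: ac.SequenceRecord(
            id=f"rep_{t.accession}",
            seq=ac.extract_amplicon(t.to_record(), *SHORT_READ_PRIMERS).full,
        )
        for t in (keep, lose)
    }
    # long reads: exact copies of both members, all assigned to `keep` by the
    # deterministic tie-break on the identical V3-V4 region... but full-length
    # reads resolve them, so emulate the collapsed case explicitly:
    reads = [
        ac.SequenceRecord(id=f"read{k}", seq=t.seq) for k, t in enumerate((keep, lose))
    ]
    assignments = {"read0": keep.accession, "read1": keep.accession}
    unique = ac.unique_taxa_by_similarity(region, reads, assignments, 0.97)
    assert unique == [lose.accession]

    # identically classified platforms -> nothing unique
    good = {"read0": keep.accession, "read1": lose.accession}
    assert ac.unique_taxa_by_similarity(region, reads, good, 0.97) == []

    # nothing within 97% -> empty
    rng = np.random.default_rng(8)
    junk = [
        ac.SequenceRecord(
            id="j", seq="".join(np.array(list("ACGT"))[rng.integers(0, 4, 1400)])
        )
    ]
    assert ac.unique_taxa_by_similarity(region, junk, {}, 0.97) == []
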