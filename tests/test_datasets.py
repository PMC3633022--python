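import numpy as np
import pytest
from scipy.stats import chisquare

from allerknn import (
    DatasetError,
    DatasetRecord,
    LabeledDataset,
    STANDARD_AMINO_ACIDS,
    SyntheticSpec,
    build_mirror_set,
    generate_route_datasets,
    generate_synthetic,
    read_labeled_fasta,
    split_folds,
    write_labeled_fasta,
)
from allerknn.datasets import (
    BACKGROUND_COMPOSITION,
    HYDROPHOBIC_GROUP,
    KmerScreen,
    biased_composition,
    route_composition,
)


def rec(i, seq, label="non-allergen", routes=(), species="Homo sapiens"):
    return DatasetRecord(id=f"r{i}", sequence=seq, label=label,
                         routes=frozenset(routes), species=species)


# ---------------------------------------------------------------------------
# containers and I/O


def test_duplicate_ids_rejected():
    with pytest.raises(DatasetError, match="duplicate"):
        LabeledDataset(records=(rec(0, "MKTAYI"), rec(0, "MKTAYL")))


def test_routes_forbidden_on_non_allergens():
    with pytest.raises(DatasetError, match="routes"):
        DatasetRecord(id="x", sequence="MKTAYI", label="non-allergen",
                      routes=frozenset({"food"}))


def test_fasta_label_roundtrip(tmp_path):
    ds = LabeledDataset(records=(
        rec(0, "MKTAYIAKQR", "allergen", {"food", "toxin"}, "Apis mellifera"),
        rec(1, "GGSSGGSSGG"),
    ))
    fasta, labels = tmp_path / "d.fasta", tmp_path / "d.labels.tsv"
    write_labeled_fasta(ds, fasta, labels)
    back = read_labeled_fasta(fasta, labels)
    assert len(back) == 2
    by_id = {r.id: r for r in back}
    assert by_id["r0"].routes == {"food", "toxin"}
    assert by_id["r0"].species == "Apis mellifera"
    assert by_id["r1"].label == "non-allergen"


def test_fasta_id_missing_from_labels_is_error(tmp_path):
    (tmp_path / "d.fasta").write_text(">a\nMKTAYI\n>b\nMKTAYL\n")
    (tmp_path / "d.labels.tsv").write_text("a\tallergen\tfood\n")
    with pytest.raises(DatasetError, match="mismatch.*'b'"):
        read_labeled_fasta(tmp_path / "d.fasta", tmp_path / "d.labels.tsv")


def test_invalid_sequences_flagged_not_dropped(tmp_path):
    (tmp_path / "d.fasta").write_text(">a\nMKTAYI\n>b\nMKXAYL\n>c\nMKTAYV\n")
    (tmp_path / "d.labels.tsv").write_text(
        "a\tallergen\tfood\nb\tnon-allergen\nc\tnon-allergen\n")
    ds = read_labeled_fasta(tmp_path / "d.fasta", tmp_path / "d.labels.tsv")
    assert len(ds) == 3
    assert len(ds.clean_records) == 2
    assert {r.id for r in ds.records if r.flagged} == {"b"}


# ---------------------------------------------------------------------------
# synthetic generation


def test_empty_spec_gives_empty_dataset():
    assert len(generate_synthetic(SyntheticSpec(n_per_class=0, seed=1))) == 0


def test_infeasible_min_length_rejected():
    with pytest.raises(DatasetError, match="minimum length"):
        SyntheticSpec(length_range=(4, 100))


def test_same_seed_identical_datasets(tmp_path):
    spec = SyntheticSpec(n_per_class=30, seed=99)
    a, b = generate_synthetic(spec), generate_synthetic(spec)
    fa, fb = tmp_path / "a.fasta", tmp_path / "b.fasta"
    write_labeled_fasta(a, fa, tmp_path / "a.tsv")
    write_labeled_fasta(b, fb, tmp_path / "b.tsv")
    assert fa.read_bytes() == fb.read_bytes()
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_composition_matches_spec_chisquare():
    """Generated residue frequencies fit the requested composition
    (goodness-of-fit not rejected at alpha = 0.001)."""
    spec = SyntheticSpec(n_per_class=100, seed=3)
    ds = generate_synthetic(spec)
    for label, comp in (("allergen", spec.allergen_composition),
                        ("non-allergen", spec.non_allergen_composition)):
        pooled = "".join(r.sequence for r in ds if r.label == label)
        counts = np.array([pooled.count(aa) for aa in STANDARD_AMINO_ACIDS])
        expected = len(pooled) * np.array(
            [comp[aa] for aa in STANDARD_AMINO_ACIDS])
        assert chisquare(counts, expected).pvalue > 0.001


def test_route_tags_present_and_multi_route_possible():
    ds = generate_synthetic(SyntheticSpec(n_per_class=200, seed=5))
    allergens = [r for r in ds if r.label == "allergen"]
    assert all(r.routes for r in allergens)
    assert any(len(r.routes) > 1 for r in allergens)
    assert all(not r.routes for r in ds if r.label == "non-allergen")


def test_hydrophobic_bias_moves_z1_autocovariance():
    """The default allergen bias (elevated I/L/V/F) must shift the lag-1 z1
    auto-covariance between classes with a large effect size."""
    from allerknn import acc_matrix

    ds = generate_synthetic(SyntheticSpec(n_per_class=200, seed=8))
    groups = {}
    for label in ("allergen", "non-allergen"):
        seqs = [(r.id, r.sequence) for r in ds if r.label == label]
        _, X = acc_matrix(seqs)
        groups[label] = X[:, 0]  # A11_l1
    pooled_sd = np.sqrt(
        (groups["allergen"].var(ddof=1) + groups["non-allergen"].var(ddof=1)) / 2
    )
    effect = abs(groups["allergen"].mean() - groups["non-allergen"].mean()) / pooled_sd
    assert effect > 0.5


def test_route_datasets_have_disjoint_route_tags():
    rd = generate_route_datasets(seed=2, n_per_class=20)
    assert set(rd) == {"food", "inhalant", "toxin", "total"}
    for route in ("food", "inhalant", "toxin"):
        allergens = [r for r in rd[route] if r.label == "allergen"]
        assert all(r.routes == {route} for r in allergens)
    assert len(rd["total"]) == 3 * 40


def test_composition_helpers_are_normalized():
    for comp in (biased_composition(HYDROPHOBIC_GROUP),
                 route_composition(HYDROPHOBIC_GROUP),
                 BACKGROUND_COMPOSITION):
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)
        assert min(comp.values()) >= 0


# ---------------------------------------------------------------------------
# mirror sets


def random_seq(rng, n=60):
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=n))


@pytest.fixture
def mirror_inputs(rng):
    allergens = LabeledDataset(records=tuple(
        DatasetRecord(id=f"al{i}", sequence=random_seq(rng), label="allergen",
                      routes=frozenset({"food"}), species=f"sp{i % 3}")
        for i in range(5)
    ))
    candidates = LabeledDataset(records=tuple(
        DatasetRecord(id=f"c{i}", sequence=random_seq(rng),
                      label="non-allergen", species=f"sp{i % 3}")
        for i in range(50)
    ))
    return allergens, candidates


def test_mirror_set_size_equals_allergen_count(mirror_inputs):
    allergens, candidates = mirror_inputs
    mirror = build_mirror_set(allergens, candidates, seed=1)
    assert len(mirror) == len(allergens)
    assert all(r.label == "non-allergen" for r in mirror)


def test_mirror_selection_reproducible(mirror_inputs):
    allergens, candidates = mirror_inputs
    m1 = build_mirror_set(allergens, candidates, seed=7)
    m2 = build_mirror_set(allergens, candidates, seed=7)
    assert [r.id for r in m1] == [r.id for r in m2]


def test_identical_candidate_always_excluded(rng):
    seq = random_seq(rng)
    allergens = LabeledDataset(records=(
        DatasetRecord(id="al", sequence=seq, label="allergen",
                      routes=frozenset({"food"}), species="sp0"),
    ))
    candidates = LabeledDataset(records=(
        DatasetRecord(id="twin", sequence=seq, label="non-allergen", species="sp0"),
        DatasetRecord(id="ok", sequence=random_seq(rng), label="non-allergen",
                      species="sp0"),
    ))
    for k in (4, 8, 12):
        mirror = build_mirror_set(allergens, candidates, kmer_k=k, seed=0)
        assert [r.id for r in mirror] == ["ok"]


def test_kmer_screen_rejects_planted_30mers(rng):
    """Candidates sharing a planted 30-mer with an allergen are never
    selected; verified against an exhaustive 30-mer intersection check."""
    allergens = LabeledDataset(records=tuple(
        DatasetRecord(id=f"al{i}", sequence=random_seq(rng, 80),
                      label="allergen", routes=frozenset({"toxin"}),
                      species="sp0")
        for i in range(5)
    ))
    motifs = [al.sequence[10:40] for al in allergens.records]
    cands = []
    for i in range(60):
        seq = random_seq(rng, 80)
        if i < 10:  # plant a shared 30-mer
            m = motifs[i % len(motifs)]
            seq = seq[:20] + m + seq[50:]
        cands.append(DatasetRecord(id=f"c{i}", sequence=seq,
                                   label="non-allergen", species="sp0"))
    candidates = LabeledDataset(records=tuple(cands))

    def shares_30mer(seq):
        mers = {seq[i:i + 30] for i in range(len(seq) - 29)}
        for al in allergens.records:
            if any(al.sequence[i:i + 30] in mers
                   for i in range(len(al.sequence) - 29)):
                return True
        return False

    contaminated = {c.id for c in cands if shares_30mer(c.sequence)}
    assert len(contaminated) >= 10
    for seed in range(5):
        mirror = build_mirror_set(allergens, candidates, seed=seed)
        assert not ({r.id for r in mirror} & contaminated)


def test_fallback_pool_used_when_species_exhausted(rng):
    allergens = LabeledDataset(records=(
        DatasetRecord(id="al", sequence=random_seq(rng), label="allergen",
                      routes=frozenset({"food"}), species="rare species"),
    ))
    empty = LabeledDataset(records=())
    fallback = LabeledDataset(records=(
        DatasetRecord(id="hu", sequence=random_seq(rng),
                      label="non-allergen", species="Homo sapiens"),
    ))
    mirror = build_mirror_set(allergens, empty, fallback_pool=fallback, seed=0)
    assert [r.id for r in mirror] == ["hu"]
    with pytest.raises(DatasetError, match="no dissimilar candidate"):
        build_mirror_set(allergens, empty, seed=0)


def test_blast_screen_agrees_on_identical_sequence(rng):
    """The external blastp adapter must reject an identical candidate and
    accept an unrelated one (exercises the subprocess path)."""
    import shutil

    if shutil.which("blastp") is None:
        pytest.skip("blastp not on PATH")
    seq = random_seq(rng, 80)
    allergens = LabeledDataset(records=(
        DatasetRecord(id="al", sequence=seq, label="allergen",
                      routes=frozenset({"food"}), species="sp0"),
    ))
    candidates = LabeledDataset(records=(
        DatasetRecord(id="twin", sequence=seq, label="non-allergen", species="sp0"),
        DatasetRecord(id="ok", sequence=random_seq(rng, 80),
                      label="non-allergen", species="sp0"),
    ))
    mirror = build_mirror_set(allergens, candidates, screen="blast", seed=0)
    assert [r.id for r in mirror] == ["ok"]


# ---------------------------------------------------------------------------
# folds


@pytest.fixture(scope="module")
def hundred():
    return generate_synthetic(SyntheticSpec(n_per_class=50, seed=13))


def test_five_folds_partition_the_dataset(hundred):
    folds = split_folds(hundred, seed=4)
    assert len(folds) == 5
    test_ids = [frozenset(r.id for r in test) for _, test in folds]
    assert all(len(ids) == 20 for ids in test_ids)
    assert frozenset().union(*test_ids) == {r.id for r in hundred}
    for i in range(5):
        for j in range(i + 1, 5):
            assert not test_ids[i] & test_ids[j]
    for train, test in folds:
        assert {r.id for r in train} == {r.id for r in hundred} - {r.id for r in test}


def test_folds_stratified_within_one_instance(hundred):
    for _, test in split_folds(hundred, seed=4):
        n_all = sum(r.label == "allergen" for r in test)
        assert abs(n_all - len(test) / 2) <= 1


def test_fold_determinism(hundred):
    a = split_folds(hundred, seed=21)
    b = split_folds(hundred, seed=21)
    assert [[r.id for r in t] for _, t in a] == [[r.id for r in t] for _, t in b]


def test_too_small_class_rejected():
    small = LabeledDataset(records=tuple(
        DatasetRecord(id=f"x{i}", sequence="MKTAYI",
                      label="allergen" if i == 0 else "non-allergen",
                      routes=frozenset({"food"}) if i == 0 else frozenset())
        for i in range(10)
    ))
    with pytest.raises(DatasetError, match="fewer than"):
        split_folds(small, n_folds=5)
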