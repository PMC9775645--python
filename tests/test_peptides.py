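"""Window extraction, dataset construction and FASTA/TSV input rules."""

import numpy as np
import pytest

from ecapsp.peptides import (AnnotatedSite, FastaParseError, PeptideWindow,
                             ProteinRecord, SiteDataset, ValidationError,
                             build_dataset, candidate_sites,
                             dataset_from_sites, easy_ensemble_split,
                             exact_duplicate_filter, extract_window,
                             read_fasta, read_sites, sanitize_sequence,
                             validate_sites, write_fasta, write_sites)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def make_protein(pid="p1", length=60, center=30):
    rng = np.random.default_rng(1)
    seq = list(rng.choice(list(AAS.replace("S", "")), size=length))
    seq[center - 1] = "S"
    return ProteinRecord(pid, "".join(seq))


# -- sanitisation -----------------------------------------------------------

def test_nonstandard_residues_become_gaps():
    assert sanitize_sequence("ABJOUXZC") == "A------C"


def test_sanitize_uppercases():
    assert sanitize_sequence("acd") == "ACD"


# -- window extraction ------------------------------------------------------

def test_interior_window_has_no_gaps():
    rec = make_protein()
    w = extract_window(rec, 30)
    assert len(w.residues) == 33
    assert "-" not in w.residues
    assert w.residues[16] == "S"
    assert w.residues == rec.sequence[13:46]


def test_n_terminal_window_gap_arithmetic():
    rec = ProteinRecord("p", "S" + "A" * 40)
    w = extract_window(rec, 1)
    assert w.residues == "-" * 16 + "S" + "A" * 16
    assert w.origin == ("p", 1)


def test_c_terminal_window_gap_arithmetic():
    rec = ProteinRecord("p", "A" * 40 + "S")
    w = extract_window(rec, 41)
    assert w.residues == "A" * 16 + "S" + "-" * 16


def test_window_length_is_always_33():
    rec = ProteinRecord("p", "A" * 10 + "S" + "A" * 10)
    for pos in range(1, 22):
        assert len(extract_window(rec, pos).residues) == 33


def test_out_of_bounds_position_raises():
    rec = make_protein()
    with pytest.raises(IndexError):
        extract_window(rec, 0)
    with pytest.raises(IndexError):
        extract_window(rec, len(rec.sequence) + 1)


def test_window_center_mismatch_rejected():
    with pytest.raises(ValidationError):
        PeptideWindow("A" * 33, "S", ("p", 1))


# -- dataset construction ---------------------------------------------------

def test_sasas_enumeration():
    rec = ProteinRecord("p", "SASAS")
    pos = [AnnotatedSite("p", 1, "S", "positive")]
    ds = build_dataset([rec], pos, "S")
    assert len(ds.positives) == 1
    assert len(ds.negatives) == 2
    assert sorted(w.origin[1] for w in ds.negatives) == [3, 5]


def test_protein_without_positives_contributes_no_negatives():
    rec_pos = ProteinRecord("a", "SASAS")
    rec_bare = ProteinRecord("b", "SSSSS")
    pos = [AnnotatedSite("a", 1, "S", "positive")]
    ds = build_dataset([rec_pos, rec_bare], pos, "S")
    assert all(w.origin[0] == "a" for w in ds.negatives)
    assert len(ds.negatives) == 2


def test_positive_on_other_residue_type_counts_toward_protein_status():
    # a threonine positive still licenses the protein's serines as negatives
    rec = ProteinRecord("a", "TASAS")
    pos = [AnnotatedSite("a", 1, "T", "positive")]
    ds = build_dataset([rec], pos, "S")
    assert len(ds.positives) == 0
    assert sorted(w.origin[1] for w in ds.negatives) == [3, 5]


def test_residue_mismatch_is_a_validation_error_listing_sites():
    rec = ProteinRecord("p", "SASAS")
    bad = [AnnotatedSite("p", 2, "S", "positive")]   # position 2 is 'A'
    with pytest.raises(ValidationError, match="p:2"):
        build_dataset([rec], bad, "S")


def test_validate_sites_lists_all_offenders():
    rec = ProteinRecord("p", "SASAS")
    bad = [AnnotatedSite("p", 2, "S", "positive"),
           AnnotatedSite("q", 1, "S", "positive"),
           AnnotatedSite("p", 99, "S", "positive")]
    with pytest.raises(ValidationError) as exc:
        validate_sites([rec], bad)
    msg = str(exc.value)
    assert "p:2" in msg and "q:1" in msg and "p:99" in msg


def test_dataset_from_sites_uses_explicit_labels():
    rec = ProteinRecord("p", "SASAS")
    sites = [AnnotatedSite("p", 1, "S", "positive"),
             AnnotatedSite("p", 3, "S", "negative")]
    ds = dataset_from_sites([rec], sites, "S")
    assert len(ds.positives) == 1 and len(ds.negatives) == 1


def test_candidate_sites_lists_all_sty_positions():
    rec = ProteinRecord("p", "SATAYAA")
    sites = candidate_sites(rec)
    assert [(s.position, s.residue) for s in sites] == [(1, "S"), (3, "T"),
                                                        (5, "Y")]


# -- EasyEnsemble -----------------------------------------------------------

def imbalanced_dataset(n_pos=5, n_neg=20):
    rec = ProteinRecord("p", "A" * 16 + "S" + "A" * 16)
    w = extract_window(rec, 17)
    pos = [PeptideWindow(w.residues, "S", ("p", i + 1)) for i in range(n_pos)]
    neg = [PeptideWindow(w.residues, "S", ("n", i + 1)) for i in range(n_neg)]
    return SiteDataset(pos, neg, "S")


def test_easy_ensemble_subsets_are_balanced():
    ds = imbalanced_dataset()
    split = easy_ensemble_split(ds, 4, seed=3)
    assert split.k == 4 and len(split.subsets) == 4
    for sub in split.subsets:
        assert len(sub.positives) == len(ds.positives)
        assert len(sub.negatives) == len(ds.positives)
        # sampling without replacement: all negatives distinct
        origins = [w.origin for w in sub.negatives]
        assert len(set(origins)) == len(origins)


def test_easy_ensemble_is_seed_reproducible_and_seed_sensitive():
    ds = imbalanced_dataset()
    a = easy_ensemble_split(ds, 3, seed=5)
    b = easy_ensemble_split(ds, 3, seed=5)
    c = easy_ensemble_split(ds, 3, seed=6)
    key = lambda s: [[w.origin for w in sub.negatives] for sub in s.subsets]
    assert key(a) == key(b)
    assert key(a) != key(c)


def test_easy_ensemble_preconditions():
    ds = imbalanced_dataset()
    with pytest.raises(ValueError):
        easy_ensemble_split(ds, 0, seed=0)
    empty_pos = SiteDataset([], ds.negatives, "S")
    with pytest.raises(ValueError):
        easy_ensemble_split(empty_pos, 2, seed=0)
    few_neg = SiteDataset(ds.negatives, ds.positives, "S")
    with pytest.raises(ValueError):
        easy_ensemble_split(few_neg, 2, seed=0)


# -- duplicate filtering ----------------------------------------------------

def test_exact_duplicates_collapse_and_positive_wins():
    rec = ProteinRecord("p", "A" * 16 + "S" + "A" * 16)
    w = extract_window(rec, 17)
    dup_neg = PeptideWindow(w.residues, "S", ("q", 17))
    other = PeptideWindow("C" * 16 + "S" + "C" * 16, "S", ("r", 17))
    ds = SiteDataset([w, w], [dup_neg, other, other], "S")
    out = exact_duplicate_filter(ds)
    assert len(out.positives) == 1
    assert [x.residues for x in out.negatives] == [other.residues]


# -- file I/O ---------------------------------------------------------------

def test_fasta_roundtrip(tmp_path):
    recs = [make_protein("p1"), make_protein("p2")]
    path = tmp_path / "x.fasta"
    write_fasta(recs, path)
    back = read_fasta(path)
    assert [(r.id, r.sequence) for r in back] == \
        [(r.id, r.sequence) for r in recs]


def test_fasta_nonstandard_residues_mapped_to_gap(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">p1\nACDXU\n")
    recs = read_fasta(path)
    assert recs[0].sequence == "ACD--"


def test_fasta_errors_carry_line_numbers(tmp_path):
    cases = {
        "ACDEF\n": "line 1",                 # data before any header
        ">a\nACD\n>a\nACD\n": "duplicate",   # duplicate id
        ">\nACD\n": "line 1",                # empty header
        ">a\n>b\nACD\n": "empty sequence",
    }
    for text, needle in cases.items():
        path = tmp_path / "bad.fasta"
        path.write_text(text)
        with pytest.raises(FastaParseError, match=needle):
            read_fasta(path)


def test_sites_tsv_roundtrip(tmp_path):
    sites = [AnnotatedSite("p1", 3, "S", "positive"),
             AnnotatedSite("p2", 7, "T", "negative")]
    path = tmp_path / "sites.tsv"
    write_sites(sites, path)
    assert read_sites(path) == sites
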