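"""Monomer feature cropping, capping and complex assembly with MSA pairing."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppiscreen.features import (
    ComplexFeatures,
    MonomerFeatures,
    MsaRow,
    SizeCapError,
    TemplateDescriptor,
    assemble,
    cap_msa,
    cap_templates,
    crop,
    load_monomer,
    parse_species_tag,
    read_a3m,
    save_monomer,
    write_a3m,
)


def monomer(acc="P00001", seq="MKTAYIAKQR", tags=("83333", "9606"), templates=2):
    """A small bundle: query + one tagged row per species + one untagged row."""
    rows = [MsaRow(seq)]
    for k, tag in enumerate(tags):
        variant = seq[:k] + "-" * 1 + seq[k + 1 :]
        rows.append(MsaRow(variant, tag, f"tr|X{k}|X{k}_ECOLI OX={tag}"))
    rows.append(MsaRow("-" * len(seq), None, "untagged"))
    return MonomerFeatures(
        accession=acc,
        sequence=seq,
        msa=tuple(rows),
        templates=tuple(
            TemplateDescriptor(f"t{k}", 1 + k, len(seq) - k) for k in range(templates)
        ),
    )


# -- crop --------------------------------------------------------------------


def test_crop_identity():
    m = monomer()
    assert crop(m, 1, m.length) == m


def test_crop_mature_chain_style():
    """Cropping off a 21-residue signal-peptide stretch shortens every row
    equally and keeps the row count."""
    seq = "A" * 21 + "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    rows = (MsaRow(seq), MsaRow("-" * 21 + seq[21:], "83333"), MsaRow("-" * len(seq)))
    m = MonomerFeatures("OMPA_LIKE", seq, rows)
    mature = crop(m, 22, len(seq))
    assert mature.length == m.length - 21
    assert mature.depth == m.depth
    assert mature.sequence == seq[21:]
    assert all(len(r.aligned) == mature.length for r in mature.msa)
    assert mature.residue_range == (22, len(seq))


def test_crop_restricts_templates():
    m = monomer(templates=2)  # spans (1, 10) and (2, 9)
    c = crop(m, 3, 8)
    assert [(t.start, t.end) for t in c.templates] == [(1, 6), (1, 6)]
    far = MonomerFeatures(
        "X", "ABCDEFGHIK", (MsaRow("ABCDEFGHIK"),),
        templates=(TemplateDescriptor("t", 9, 10),),
    )
    assert crop(far, 1, 5).templates == ()


def test_crop_out_of_bounds():
    m = monomer()
    for start, end in [(0, 5), (5, 3), (1, m.length + 1)]:
        with pytest.raises(ValueError):
            crop(m, start, end)


@given(st.data())
def test_crop_composition(data):
    """crop(crop(f, s1, e1), s2, e2) == crop(f, s1+s2-1, s1+e2-1)."""
    m = monomer(seq="MKTAYIAKQRQISFVKSHFS")
    s1 = data.draw(st.integers(1, m.length))
    e1 = data.draw(st.integers(s1, m.length))
    inner_len = e1 - s1 + 1
    s2 = data.draw(st.integers(1, inner_len))
    e2 = data.draw(st.integers(s2, inner_len))
    assert crop(crop(m, s1, e1), s2, e2) == crop(m, s1 + s2 - 1, s1 + e2 - 1)


# -- caps --------------------------------------------------------------------


def test_cap_msa_depth():
    m = monomer()
    assert cap_msa(m, 5000) == m
    deep = MonomerFeatures(
        "X", "MKTA", tuple([MsaRow("MKTA")] + [MsaRow("MKT-", str(k)) for k in range(60)])
    )
    capped = cap_msa(deep, 20)
    assert capped.depth == 20
    assert capped.msa[0] == deep.msa[0]  # query retained
    assert cap_msa(deep, 1).depth == 1
    with pytest.raises(ValueError):
        cap_msa(deep, 0)


def test_cap_templates():
    m = monomer(templates=6)
    assert len(cap_templates(m, 4).templates) == 4
    assert cap_templates(m, 0).templates == ()
    assert len(cap_templates(monomer(templates=2), 4).templates) == 2


# -- assemble ----------------------------------------------------------------


def test_assemble_single_monomer_is_identity():
    m = monomer()
    cx = assemble([m], pairing="none")
    assert cx.total_length == m.length
    assert cx.sequence == m.sequence
    assert [r.aligned for r in cx.msa] == [r.aligned for r in m.msa]


def test_assemble_none_is_block_diagonal():
    m1, m2 = monomer("P1", "MKTAYIAKQR"), monomer("P2", "QISFVK")
    cx = assemble([m1, m2], pairing="none")
    assert len(cx.msa) == m1.depth + m2.depth
    assert cx.msa[0].aligned == m1.sequence + "-" * m2.length
    assert cx.msa[m1.depth].aligned == "-" * m1.length + m2.sequence
    assert all(len(r.aligned) == cx.total_length for r in cx.msa)


def test_assemble_all_paired_joins_shared_species():
    """Tags {A,B,C} x {B,C,D} pair exactly B and C, placed before unpaired rows."""
    m1 = monomer("P1", "MKTAYIAKQR", tags=("A", "B", "C"))
    m2 = monomer("P2", "QISFVK", tags=("B", "C", "D"))
    cx = assemble([m1, m2], pairing="all_paired")
    assert [r.species_tag for r in cx.msa[:2]] == ["B", "C"]
    assert len(cx.msa) == m1.depth + m2.depth - 2  # 4 consumed rows -> 2 joint rows
    assert cx.msa[0].aligned[: m1.length] != "-" * m1.length
    assert cx.msa[0].aligned[m1.length :] != "-" * m2.length
    # row count never exceeds the unpaired assembly
    assert len(cx.msa) <= len(assemble([m1, m2], pairing="none").msa)


def test_assemble_no_shared_species_degenerates_to_block():
    m1 = monomer("P1", tags=("A",))
    m2 = monomer("P2", tags=("B",))
    cx = assemble([m1, m2], pairing="all_paired")
    assert len(cx.msa) == m1.depth + m2.depth


def test_assemble_size_cap():
    m1 = MonomerFeatures("P1", "A" * 800, (MsaRow("A" * 800),))
    m2 = MonomerFeatures("P2", "A" * 900, (MsaRow("A" * 900),))
    with pytest.raises(SizeCapError):
        assemble([m1, m2])  # 1700 > 1600
    assert assemble([m1, m2], size_cap=None).total_length == 1700
    assert assemble([m1, m2], size_cap=1700).total_length == 1700


def test_assemble_rejects_experimental_pairing_modes():
    m = monomer()
    for mode in ("cyclic", "linear", "arbitrary"):
        with pytest.raises(NotImplementedError):
            assemble([m, m], pairing=mode, size_cap=None)
    with pytest.raises(ValueError):
        assemble([m], pairing="bogus")
    with pytest.raises(ValueError):
        assemble([], pairing="none")


def test_operations_are_pure():
    m = monomer()
    snapshot = (m.sequence, m.msa, m.templates, m.residue_range)
    crop(m, 2, 5)
    cap_msa(m, 2)
    cap_templates(m, 0)
    assemble([m, m], pairing="all_paired", size_cap=None)
    assert (m.sequence, m.msa, m.templates, m.residue_range) == snapshot


# -- on-disk formats ---------------------------------------------------------


def test_species_tag_parsing():
    assert parse_species_tag("tr|A|A_ECOLI OX=83333 GN=ompA") == "83333"
    assert parse_species_tag("seq TaxID=9606") == "9606"
    assert parse_species_tag("plain header") is None


def test_a3m_round_trip_strips_insertions(tmp_path):
    path = tmp_path / "msa.a3m"
    path.write_text(">q\nMKTA\n>hit OX=83333\nM-taKA\n")
    rows = read_a3m(path)
    assert rows[0].aligned == "MKTA"
    assert rows[1].aligned == "M-KA"  # lowercase insertion states removed
    assert rows[1].species_tag == "83333"
    write_a3m(rows, tmp_path / "out.a3m")
    assert [r.aligned for r in read_a3m(tmp_path / "out.a3m")] == ["MKTA", "M-KA"]


def test_monomer_bundle_round_trip(tmp_path):
    m = monomer()
    save_monomer(m, tmp_path / "P00001")
    back = load_monomer(tmp_path / "P00001")
    assert back.accession == m.accession
    assert back.sequence == m.sequence
    assert [r.aligned for r in back.msa] == [r.aligned for r in m.msa]
    assert [r.species_tag for r in back.msa] == [r.species_tag for r in m.msa]
    assert back.templates == m.templates
    assert back.residue_range == m.residue_range
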