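"""Amide library enumeration, scaffold deltas and product PCP summaries."""

import numpy as np
import pytest
from rdkit import Chem

from bbdesign.catalog import BBClass, BuildingBlock, compute_pcp
from bbdesign.enumeration import (
    WATER_MW,
    LibraryDesign,
    amidate_acid,
    couple_amide,
    enumerate_library,
    library_pcp_summary,
    scaffold_delta,
)
from bbdesign.errors import AmbiguityError


def _bb(smiles, cls, bb_id):
    return BuildingBlock(bb_id, Chem.CanonSmiles(smiles), cls)


def test_couple_amide_ethylamine_acetic():
    product = couple_amide("CCN", "CC(=O)O")
    assert product == Chem.CanonSmiles("CCNC(C)=O")
    # mass balance: 45.08 + 60.05 - 18.02 = 87.12 Da
    assert compute_pcp(product).mw == pytest.approx(87.12, abs=0.01)


def test_couple_amide_mass_balance_random_pairs(small_amine_catalog,
                                                small_acid_catalog):
    for amine, acid in zip(small_amine_catalog.members[:15],
                           small_acid_catalog.members[:15]):
        product = couple_amide(amine.smiles, acid.smiles)
        assert compute_pcp(product).mw == pytest.approx(
            amine.pcp.mw + acid.pcp.mw - WATER_MW, abs=0.01
        )


@pytest.mark.parametrize(
    "amine, acid",
    [
        ("NCCCCN", "CC(=O)O"),  # diamine
        ("CCN", "OC(=O)CCC(=O)O"),  # diacid
        ("CCO", "CC(=O)O"),  # no amine at all
    ],
)
def test_couple_amide_ambiguity(amine, acid):
    with pytest.raises(AmbiguityError):
        couple_amide(amine, acid)


def test_enumerate_cross_product_and_failure_accounting(small_amine_catalog,
                                                        small_acid_catalog):
    design = LibraryDesign(
        "DEL2", small_amine_catalog.members[:3], small_acid_catalog.members[:4]
    )
    products, report = enumerate_library(design)
    assert report.n_pairs == 12
    assert len(products) == 12 - len(report.failures)
    assert report.failures == []
    # polyfunctional cycle-1 member is excluded upfront and reported
    design2 = LibraryDesign(
        "DEL2",
        small_amine_catalog.members[:3]
        + [_bb("NCCCCN", BBClass.PRIMARY_AMINE, "diamine")],
        small_acid_catalog.members[:4],
    )
    products2, report2 = enumerate_library(design2)
    assert [e[0] for e in report2.excluded_cycle1] == ["diamine"]
    assert len(products2) == 12


def test_enumerate_empty_cycle_rejected(small_amine_catalog):
    with pytest.raises(ValueError):
        enumerate_library(LibraryDesign("DEL2", small_amine_catalog.members[:2], []))


def test_del1_products_carry_pendant_amide(small_fmoc_catalog,
                                           small_acid_catalog):
    design = LibraryDesign(
        "DEL1", small_fmoc_catalog.members[:2], small_acid_catalog.members[:2]
    )
    products, report = enumerate_library(design)
    assert len(products) == 4
    amide_patt = Chem.MolFromSmarts("[CX3](=O)[NX3;H2]")
    for p in products:
        mol = Chem.MolFromSmiles(p.smiles)
        assert mol.HasSubstructMatch(amide_patt)  # pendant primary amide


def test_del1_vs_del2_matched_products_differ_by_conh2(small_acid_catalog):
    """A DEL1 product and its DEL2 analog (same scaffolds) differ by the
    pendant amide: +~44 Da minus one H, +1 donor, +2 acceptors."""
    fmoc_ala = _bb("CC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O", BBClass.FMOC_AA, "fa")
    ethylamine = _bb("CCN", BBClass.PRIMARY_AMINE, "am")
    acid = small_acid_catalog.members[0]
    p1, _ = enumerate_library(LibraryDesign("DEL1", [fmoc_ala], [acid]))
    p2, _ = enumerate_library(LibraryDesign("DEL2", [ethylamine], [acid]))
    # both cycle-1 synthons reduce to an ethyl backbone; the DEL1 product
    # carries the extra C(=O)NH2 where DEL2 has an H
    assert p1[0].pcp.mw - p2[0].pcp.mw == pytest.approx(44.03 - 1.008, abs=0.01)
    assert p1[0].pcp.hbd - p2[0].pcp.hbd == 1
    assert p1[0].pcp.hba - p2[0].pcp.hba == 2


def test_scaffold_delta_analytic():
    d1 = LibraryDesign("DEL1", [], [])
    d2 = LibraryDesign("DEL2", [], [])
    delta = scaffold_delta(d1, d2)
    assert round(delta["mw"]) == 44
    assert delta["hbd"] == 1
    assert delta["hba"] == 2
    zero = scaffold_delta(d1, d1)
    assert zero == {"mw": 0.0, "hbd": 0, "hba": 0}


def test_amidate_acid():
    assert amidate_acid("CC(=O)O") == Chem.CanonSmiles("CC(N)=O")


def test_pcp_summary_medians_match_sort_oracle(small_amine_catalog,
                                               small_acid_catalog):
    design = LibraryDesign(
        "DEL2", small_amine_catalog.members[:10], small_acid_catalog.members[:10]
    )
    products, _ = enumerate_library(design)
    summary = library_pcp_summary(products)
    mws = sorted(p.pcp.mw for p in products)
    mid = len(mws) // 2
    expected = mws[mid] if len(mws) % 2 else (mws[mid - 1] + mws[mid]) / 2
    assert summary["medians"]["mw"] == pytest.approx(expected)
    assert 0.0 <= summary["ro5_pass_fraction"] <= 1.0
    assert summary["ro5_thresholds"]["mw"] == 500.0


def test_pcp_summary_single_and_duplicated():
    p, _ = enumerate_library(
        LibraryDesign(
            "DEL2",
            [_bb("CCN", BBClass.PRIMARY_AMINE, "a")],
            [_bb("CC(=O)O", BBClass.CARBOXYLIC_ACID, "b")],
        )
    )
    single = library_pcp_summary(p)
    assert single["medians"]["mw"] == pytest.approx(p[0].pcp.mw)
    doubled = library_pcp_summary(p + p)
    assert doubled["medians"] == single["medians"]
    with pytest.raises(ValueError):
        library_pcp_summary([])


def test_mw250_bbs_give_ro5_compatible_product_mw(small_amine_catalog,
                                                  small_acid_catalog):
    """BBs filtered at MW <= 250 Da compose to products <= 500 - water."""
    from bbdesign.truncate import pcp_filter

    amines, _ = pcp_filter(small_amine_catalog, 250.0)
    acids, _ = pcp_filter(small_acid_catalog, 250.0)
    design = LibraryDesign("DEL2", amines.members[:8], acids.members[:8])
    products, _ = enumerate_library(design)
    for p in products:
        assert p.pcp.mw <= 500.0 - WATER_MW + 0.01
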