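"""Fragment decomposition and combinatorial enumeration."""

import itertools
import logging
import re

import pytest
from rdkit import Chem
from rdkit.Chem import BRICS

from alchemspace import Ligand, decompose_series, enumerate_library
from alchemspace.library_builder import fragment_from_smiles

CORE = "c1ccncc1"


def _normalize(smiles: str) -> str:
    """Canonical form with all dummy labels erased, for cross-route
    comparison of fragment structures."""
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(0)
            atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


def _oracle_decompose(smiles: str, core: str):
    """Independent single-molecule decomposition: strip the core with
    ReplaceCore, cut the side chain at BRICS bonds, and classify the piece
    holding the ReplaceCore dummy as the linker."""
    mol = Chem.MolFromSmiles(smiles)
    side = Chem.ReplaceCore(mol, Chem.MolFromSmiles(core))
    if side is None or side.GetNumAtoms() == 0:
        return set(), set()
    linkers, termini = set(), set()
    for piece in Chem.GetMolFrags(side, asMols=True):
        # every dummy at this point is a core-attachment marker (BRICS has
        # not run yet); tag them so they stay recognizable after the cuts
        for atom in piece.GetAtoms():
            if atom.GetAtomicNum() == 0:
                atom.SetAtomMapNum(77)
        for frag in Chem.GetMolFrags(
            BRICS.BreakBRICSBonds(piece), asMols=True
        ):
            has_core_dummy = any(
                a.GetAtomicNum() == 0 and a.GetAtomMapNum() == 77
                for a in frag.GetAtoms()
            )
            smi = _normalize(Chem.MolToSmiles(frag))
            (linkers if has_core_dummy else termini).add(smi)
    return linkers, termini


def test_fragment_bonded_to_core_is_a_linker():
    """A methyl directly on the benzene core is a linker: linkers bond to
    the core, termini bond to linkers."""
    frags = decompose_series([Ligand("tol", "Cc1ccccc1")], "c1ccccc1")
    assert len(frags) == 1
    assert frags[0].kind == "linker"
    assert frags[0].core_anchor is not None
    assert _normalize(frags[0].smiles_with_attachment) == _normalize("[*]C")


def test_ligand_identical_to_core_gives_no_fragments():
    assert decompose_series([Ligand("b", "c1ccccc1")], "c1ccccc1") == []


def test_ligand_without_core_is_skipped_with_warning(caplog):
    with caplog.at_level(logging.WARNING):
        frags = decompose_series(
            [Ligand("hex", "CCCCCC"), Ligand("tol", "Cc1ccccc1")],
            "c1ccccc1",
        )
    assert any("hex" in r.message for r in caplog.records)
    assert len(frags) == 1  # the valid ligand still contributes


def test_series_decomposition_matches_independent_oracle(pyridine_series):
    """Linker/terminus structures across the 20-ligand pyridine series agree
    with a one-molecule-at-a-time ReplaceCore + BRICS decomposition."""
    frags = decompose_series(pyridine_series, CORE)
    got_linkers = {
        _normalize(f.smiles_with_attachment)
        for f in frags if f.kind == "linker"
    }
    got_termini = {
        _normalize(f.smiles_with_attachment)
        for f in frags if f.kind == "terminus"
    }
    want_linkers, want_termini = set(), set()
    for lig in pyridine_series:
        lk, tm = _oracle_decompose(lig.smiles, CORE)
        want_linkers |= lk
        want_termini |= tm
    assert got_linkers == want_linkers
    assert got_termini == want_termini


def test_fragment_dedup_keeps_first_origin():
    ligands = [Ligand("a", "Cc1ccncc1"), Ligand("b", "Cc1ccncc1")]
    frags = decompose_series(ligands, CORE)
    assert len(frags) == 1
    assert frags[0].origin_ligand_id == "a"


# ---------------------------------------------------------------------------
# enumeration


LINKER_1SITE = fragment_from_smiles("[3*]CC[*:1]", "linker", core_anchor=0)
LINKER_2SITE = fragment_from_smiles("[3*]CC([4*])C[*:1]", "linker",
                                    core_anchor=0)
LINKER_2SITE_B = fragment_from_smiles("[3*]CCC([4*])[*:1]", "linker",
                                      core_anchor=0)
TERM_METHYL = fragment_from_smiles("[5*]C", "terminus")
TERM_HYDROXY = fragment_from_smiles("[5*]O", "terminus")
TERM_AMINO = fragment_from_smiles("[5*]N", "terminus")


def test_counting_one_linker_three_termini_one_slot():
    prods = enumerate_library(
        "c1ccncc1", [LINKER_1SITE], [TERM_METHYL, TERM_HYDROXY, TERM_AMINO],
        max_termini=1,
    )
    assert len(prods) == 4  # bare linker + one product per terminus


def test_max_termini_zero_gives_one_product_per_linker():
    prods = enumerate_library(
        "c1ccncc1", [LINKER_1SITE, LINKER_2SITE],
        [TERM_METHYL, TERM_HYDROXY], max_termini=0,
    )
    assert len(prods) == 2


def _oracle_enumerate(core, linkers, termini, max_termini):
    """Brute-force assembly through RDKit molzip: relabel every open site
    pair with a fresh matching dummy label and let molzip fuse them."""
    out = set()
    core_mol = Chem.MolFromSmiles(core)
    for linker in linkers:
        lmol = Chem.MolFromSmiles(linker.smiles_with_attachment)
        branch = sorted(
            a.GetIdx() for a in lmol.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() == 0
        )
        for k in range(min(max_termini, len(branch)) + 1):
            for sites in itertools.combinations(branch, k):
                for choice in itertools.product(termini, repeat=k):
                    # start from core with an added dummy at the anchor
                    ed = Chem.RWMol(core_mol)
                    d = Chem.Atom(0)
                    d.SetAtomMapNum(99)
                    di = ed.AddAtom(d)
                    ed.AddBond(linker.core_anchor, di, Chem.BondType.SINGLE)
                    work = Chem.RWMol(lmol)
                    label = 50
                    for atom in work.GetAtoms():
                        if _is_core_site(atom):
                            atom.SetIsotope(0)
                            atom.SetAtomMapNum(99)
                    assembled = Chem.molzip(ed.GetMol(), work.GetMol())
                    for s, term in zip(sites, choice):
                        assembled = _zip_one(assembled, s, term, label)
                        label += 1
                    assembled = Chem.RWMol(assembled)
                    for idx in sorted(
                        (a.GetIdx() for a in assembled.GetAtoms()
                         if a.GetAtomicNum() == 0), reverse=True,
                    ):
                        assembled.RemoveAtom(idx)
                    final = assembled.GetMol()
                    Chem.SanitizeMol(final)
                    out.add(Chem.MolToSmiles(final))
    return out


def _is_core_site(atom):
    return atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() > 0


def _zip_one(assembled, orig_branch_idx, terminus, label):
    """Fuse one terminus onto the branch dummy that originated at
    ``orig_branch_idx`` in the linker (tracked by isotope)."""
    work = Chem.RWMol(assembled)
    target = None
    for atom in work.GetAtoms():
        if (atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 0
                and atom.GetIsotope() == _BRANCH_ISOTOPES[orig_branch_idx]):
            target = atom
            break
    assert target is not None
    target.SetAtomMapNum(label)
    tmol = Chem.RWMol(Chem.MolFromSmiles(terminus.smiles_with_attachment))
    first = next(a for a in tmol.GetAtoms() if a.GetAtomicNum() == 0)
    first.SetAtomMapNum(label)
    return Chem.molzip(work.GetMol(), tmol.GetMol())


# branch dummies are identified across routes by their SMILES isotope labels
_BRANCH_ISOTOPES = {}
for _frag in (LINKER_1SITE, LINKER_2SITE, LINKER_2SITE_B):
    _m = Chem.MolFromSmiles(_frag.smiles_with_attachment)
    for _a in _m.GetAtoms():
        if _a.GetAtomicNum() == 0 and _a.GetAtomMapNum() == 0:
            _BRANCH_ISOTOPES[_a.GetIdx()] = _a.GetIsotope()


def test_enumeration_matches_bruteforce_assembly():
    """Two 2-site linkers × two termini up to 2 placements: the product set
    equals an exhaustive generate-and-canonicalize enumeration via molzip."""
    linkers = [LINKER_2SITE, LINKER_2SITE_B]
    termini = [TERM_METHYL, TERM_HYDROXY]
    got = {
        p.smiles for p in enumerate_library(
            "c1ccncc1", linkers, termini, max_termini=2
        )
    }
    want = _oracle_enumerate("c1ccncc1", linkers, termini, 2)
    assert got == want


def test_enumeration_is_deterministic_and_dedupes():
    args = ("c1ccncc1", [LINKER_2SITE], [TERM_METHYL, TERM_HYDROXY], 2)
    first = enumerate_library(*args)
    second = enumerate_library(*args)
    assert [p.smiles for p in first] == [p.smiles for p in second]
    assert [p.ligand_id for p in first] == [p.ligand_id for p in second]
    smiles = [p.smiles for p in first]
    assert len(smiles) == len(set(smiles))


def test_reassembly_closure(pyridine_series):
    """Decomposing enumerated products against the same core yields only
    fragments already present in the input fragment set."""
    frags = decompose_series(pyridine_series, CORE)
    linkers = [f for f in frags if f.kind == "linker"]
    termini = [f for f in frags if f.kind == "terminus"]
    prods = enumerate_library(CORE, linkers[:4], termini, max_termini=1)
    input_set = {_normalize(f.smiles_with_attachment) for f in frags}
    re_frags = decompose_series(
        [Ligand(p.ligand_id, p.smiles) for p in prods], CORE
    )
    got = {_normalize(f.smiles_with_attachment) for f in re_frags}
    assert got <= input_set


def test_manifest_records_provenance():
    prods, manifest = enumerate_library(
        "c1ccncc1", [LINKER_1SITE], [TERM_METHYL, TERM_HYDROXY],
        max_termini=1, return_manifest=True,
    )
    assert len(manifest) == len(prods)
    assert all(row["linker_id"] == "L0" for row in manifest)
    assert {row["termini_ids"] for row in manifest} == {"", "T0", "T1"}
    assert all(re.fullmatch(r"enum_\d{6}", row["ligand_id"])
               for row in manifest)
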