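"""Fragment-based combinatorial library construction.

A congeneric ligand series sharing a common core is decomposed into two
groups of fragments: *linkers*, which bond directly to the core, and
*termini*, which bond to the linkers. The decomposition removes the core
from each ligand and cuts the remainder at BRICS bonds, keeping track of
which atom bonded to the core. A new library is then enumerated as
core + one linker (attached at the same core atom it came from) decorated
with up to ``max_termini`` terminal groups on the linker's open sites.

All attachments are formed as single bonds; the series this targets attach
R-groups to their scaffold through single bonds.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import BRICS

from .containers import Fragment, Ligand

logger = logging.getLogger(__name__)

__all__ = ["decompose_series", "enumerate_library", "fragment_from_smiles"]

_CORE_SITE = "core"
_BRANCH_SITE = "branch"


def _parse(smiles: str, what: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {what}: {smiles!r}")
    return mol


def _is_core_dummy(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() > 0


def _fragment_sites(mol: Chem.Mol) -> tuple[list[tuple[int, str]], Optional[int]]:
    """Attachment sites of a fragment molecule, plus its core anchor.

    The core-facing dummy carries an atom map number encoding the core atom
    it bonded to (anchor + 1); BRICS dummies carry isotopes and no map.
    """
    sites: list[tuple[int, str]] = []
    anchor: Optional[int] = None
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 0:
            continue
        if _is_core_dummy(atom):
            sites.append((atom.GetIdx(), _CORE_SITE))
            anchor = atom.GetAtomMapNum() - 1
        else:
            sites.append((atom.GetIdx(), _BRANCH_SITE))
    return sites, anchor


def fragment_from_smiles(
    smiles: str,
    kind: str,
    origin_ligand_id: str = "manual",
    core_anchor: Optional[int] = None,
) -> Fragment:
    """Build a Fragment from an attachment-marked SMILES.

    Dummy atoms with an atom map (``[*:k]``) are core-facing (the anchor,
    if not given, is taken as ``k − 1``); unmapped dummies (``[3*]`` etc.)
    are termini-facing branch sites.
    """
    mol = _parse(smiles, f"{kind} fragment")
    sites, parsed_anchor = _fragment_sites(mol)
    return Fragment(
        smiles_with_attachment=smiles,
        kind=kind,
        origin_ligand_id=origin_ligand_id,
        attachment_sites=sites,
        core_anchor=core_anchor if core_anchor is not None else parsed_anchor,
    )


def _remove_core(mol: Chem.Mol, match: Sequence[int]) -> Chem.Mol:
    """Delete matched core atoms, capping each crossing bond with a marked
    dummy that records the core-atom position it was bonded to."""
    edit = Chem.RWMol(mol)
    core_atoms = set(match)
    caps: list[tuple[int, int]] = []  # (outside atom idx, core position)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in core_atoms) != (b in core_atoms):
            outside = b if a in core_atoms else a
            inside = a if a in core_atoms else b
            caps.append((outside, match.index(inside)))
    for outside, core_pos in caps:
        dummy = Chem.Atom(0)
        dummy.SetAtomMapNum(core_pos + 1)
        d_idx = edit.AddAtom(dummy)
        edit.AddBond(outside, d_idx, Chem.BondType.SINGLE)
    for idx in sorted(core_atoms, reverse=True):
        edit.RemoveAtom(idx)
    remainder = edit.GetMol()
    Chem.SanitizeMol(remainder)
    return remainder


def decompose_series(
    ligands: Sequence[Ligand],
    core: str,
) -> list[Fragment]:
    """Decompose a core-sharing series into linker and terminus fragments.

    Each ligand's core match is removed; the remainder is cut at BRICS
    bonds. Fragments still holding a core-facing attachment are linkers,
    the rest are termini. Fragments are deduplicated by canonical form,
    keeping the first origin ligand. Ligands that do not contain the core
    are reported and skipped.
    """
    core_mol = _parse(core, "core")
    fragments: dict[str, Fragment] = {}
    for lig in ligands:
        mol = _parse(lig.smiles, f"ligand {lig.ligand_id}")
        match = mol.GetSubstructMatch(core_mol)
        if not match:
            logger.warning("ligand %s lacks the core substructure; skipped",
                           lig.ligand_id)
            continue
        remainder = _remove_core(mol, match)
        if remainder.GetNumAtoms() == 0:
            continue
        broken = BRICS.BreakBRICSBonds(remainder)
        for frag in Chem.GetMolFrags(broken, asMols=True,
                                     sanitizeFrags=True):
            sites, anchor = _fragment_sites(frag)
            if not sites:
                continue
            kind = "linker" if anchor is not None else "terminus"
            smi = Chem.MolToSmiles(frag)
            if smi in fragments:
                continue
            fragments[smi] = Fragment(
                smiles_with_attachment=smi,
                kind=kind,
                origin_ligand_id=lig.ligand_id,
                attachment_sites=sites,
                core_anchor=anchor,
            )
    return list(fragments.values())


def _join_at_dummies(
    mol_a: Chem.RWMol, dummy_a: int, mol_b: Chem.Mol, dummy_b: int
) -> tuple[Chem.RWMol, int]:
    """Merge ``mol_b`` into ``mol_a``, bonding the dummies' neighbors with a
    single bond and deleting both dummies. Returns the merged editable mol
    and the atom-count offset at which ``mol_b`` was inserted."""
    offset = mol_a.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    da, db = dummy_a, dummy_b + offset
    na = combined.GetAtomWithIdx(da).GetNeighbors()[0].GetIdx()
    nb = combined.GetAtomWithIdx(db).GetNeighbors()[0].GetIdx()
    combined.AddBond(na, nb, Chem.BondType.SINGLE)
    for idx in sorted((da, db), reverse=True):
        combined.RemoveAtom(idx)
    return combined, offset


def _strip_dummies(mol: Chem.RWMol) -> Chem.RWMol:
    """Remove remaining dummy atoms (open sites become implicit hydrogens)."""
    for idx in sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0),
        reverse=True,
    ):
        mol.RemoveAtom(idx)
    return mol


def _first_branch_dummy(mol: Chem.Mol) -> Optional[int]:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and not _is_core_dummy(atom):
            return atom.GetIdx()
    return None


def _assemble(
    core_mol: Chem.Mol,
    linker_mol: Chem.Mol,
    core_anchor: int,
    site_assignment: Sequence[tuple[int, Chem.Mol]],
) -> Optional[tuple[str, str]]:
    """Build one product; returns (canonical smiles, rgroup smiles) or None
    on a chemistry failure (e.g. valence violation)."""
    # attach the linker to the core at the recorded anchor atom
    offset = core_mol.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(core_mol, linker_mol))
    core_dummy = None
    for atom in linker_mol.GetAtoms():
        if _is_core_dummy(atom):
            core_dummy = atom.GetIdx() + offset
            break
    if core_dummy is None:
        return None
    neighbor = combined.GetAtomWithIdx(core_dummy).GetNeighbors()[0].GetIdx()
    combined.AddBond(core_anchor, neighbor, Chem.BondType.SINGLE)
    combined.RemoveAtom(core_dummy)

    # track linker branch dummies through the merge by atom map tags
    tag = 9000
    tags: dict[int, int] = {}  # original linker dummy idx -> tag
    for site_idx, _ in site_assignment:
        shifted = site_idx + offset
        shifted -= int(core_dummy < shifted)
        combined.GetAtomWithIdx(shifted).SetAtomMapNum(tag)
        tags[site_idx] = tag
        tag += 1

    try:
        for site_idx, term_mol in site_assignment:
            d_idx = next(
                a.GetIdx() for a in combined.GetAtoms()
                if a.GetAtomMapNum() == tags[site_idx]
            )
            t_dummy = _first_branch_dummy(term_mol)
            if t_dummy is None:
                return None
            combined, _ = _join_at_dummies(combined, d_idx, term_mol, t_dummy)
        product = _strip_dummies(combined)
        for atom in product.GetAtoms():
            atom.SetAtomMapNum(0)
        mol = product.GetMol()
        Chem.SanitizeMol(mol)
        smiles = Chem.MolToSmiles(mol)
    except Exception:
        return None

    # the R-group substructure: the product minus the core
    rgroup = ""
    rmatch = mol.GetSubstructMatch(core_mol)
    if rmatch:
        edit = Chem.RWMol(mol)
        for idx in sorted(rmatch, reverse=True):
            edit.RemoveAtom(idx)
        try:
            rmol = edit.GetMol()
            Chem.SanitizeMol(rmol)
            rgroup = Chem.MolToSmiles(rmol)
        except Exception:
            rgroup = ""
    return smiles, rgroup


def enumerate_library(
    core: str,
    linkers: Sequence[Fragment],
    termini: Sequence[Fragment],
    max_termini: int = 3,
    id_prefix: str = "enum",
    return_manifest: bool = False,
):
    """Enumerate core + linker + 0..max_termini termini assemblies.

    Each linker attaches to the core at the atom it bonded to in its source
    ligand. Termini are placed on every subset of the linker's open sites of
    size ≤ ``max_termini``, with repetition of termini allowed across sites.
    Products are deduplicated by canonical form (so symmetric site
    permutations collapse) and returned in a deterministic order; assemblies
    that violate valence are skipped and counted in the log.

    With ``return_manifest`` the return value is ``(ligands, manifest)``
    where each manifest row records (ligand_id, smiles, linker_id,
    termini_ids) using positional ids L<i>/T<j> into the input fragment
    lists.
    """
    if max_termini < 0:
        raise ValueError("max_termini must be >= 0")
    core_mol = _parse(core, "core")
    term_mols = []
    for t in termini:
        if t.kind != "terminus":
            raise ValueError(
                f"fragment {t.smiles_with_attachment!r} is not a terminus"
            )
        term_mols.append(_parse(t.smiles_with_attachment, "terminus"))

    seen: set[str] = set()
    products: list[Ligand] = []
    manifest: list[dict] = []
    n_skipped = 0
    for li, linker in enumerate(linkers):
        if linker.kind != "linker":
            raise ValueError(
                f"fragment {linker.smiles_with_attachment!r} is not a linker"
            )
        if linker.core_anchor is None:
            raise ValueError(
                f"linker {linker.smiles_with_attachment!r} has no core anchor"
            )
        linker_mol = _parse(linker.smiles_with_attachment, "linker")
        branch_sites = sorted(
            idx for idx, label in _fragment_sites(linker_mol)[0]
            if label == _BRANCH_SITE
        )
        max_k = min(max_termini, len(branch_sites))
        for k in range(max_k + 1):
            for sites in itertools.combinations(branch_sites, k):
                for choice in itertools.product(range(len(term_mols)),
                                                repeat=k):
                    assignment = [
                        (s, term_mols[c]) for s, c in zip(sites, choice)
                    ]
                    built = _assemble(core_mol, linker_mol,
                                      linker.core_anchor, assignment)
                    if built is None:
                        n_skipped += 1
                        continue
                    smiles, rgroup = built
                    if smiles in seen:
                        continue
                    seen.add(smiles)
                    lig_id = f"{id_prefix}_{len(products):06d}"
                    products.append(
                        Ligand(
                            ligand_id=lig_id,
                            smiles=smiles,
                            rgroup_smiles=rgroup or None,
                            provenance="enumerated",
                        )
                    )
                    manifest.append({
                        "ligand_id": lig_id,
                        "smiles": smiles,
                        "linker_id": f"L{li}",
                        "termini_ids": ";".join(f"T{c}" for c in choice),
                    })
    if n_skipped:
        logger.info("enumeration skipped %d chemically invalid assemblies",
                    n_skipped)
    if return_manifest:
        return products, manifest
    return products
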