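"""Per-molecule eplet mismatch, recipient-level single-molecule maxima,
antigen-level mismatch, and DSA-specificity-to-molecule attribution.

A donor molecule's mismatch is the set of its eplets absent from every
recipient molecule of the same locus class (DR chains are compared against
the union of all recipient DRB1/3/4/5 chains, DQ heterodimers against the
union of both recipient DQ heterodimers).  The recipient-level summary
keeps the maximum per class: ``dr_max`` and ``dq_max``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .errors import ContractError, ParseError
from .registry import (
    EpletRegistry,
    Molecule,
    SubjectTyping,
    enumerate_molecules,
    first_field,
)

_SEROLOGIC_RE = re.compile(r"^(DR|DQ)(\d{1,3})$")
_ALLELE_LIKE_RE = re.compile(r"^([A-Z]+\d*)\*(\d+)(?::(\d+))?")

#: serologic splits naming the secondary DR loci
_DR_SEROLOGIC_SPECIAL = {"51": "DRB5*", "52": "DRB3*", "53": "DRB4*"}


@dataclass(frozen=True)
class MoleculeMismatch:
    molecule_id: str
    kind: str
    mismatched_eplets: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.mismatched_eplets)


@dataclass
class RecipientMismatchSummary:
    pair_id: str
    molecule_mismatches: list[MoleculeMismatch]
    dr_max: int
    dq_max: int
    dr_antigen_mm: int
    dq_antigen_mm: int


def molecule_eplet_mismatch(
    donor_mol: Molecule,
    recipient_mols: list[Molecule],
    registry: EpletRegistry | None = None,
) -> MoleculeMismatch:
    """Eplets on ``donor_mol`` absent from every molecule in ``recipient_mols``.

    All recipient molecules must share the donor molecule's kind (class
    mixing is a contract error).  An empty recipient list is allowed and
    yields the donor molecule's full eplet set.
    """
    for m in recipient_mols:
        if m.kind != donor_mol.kind:
            raise ContractError(
                f"class mixing: donor {donor_mol.kind} vs recipient {m.kind}"
            )
    if registry is not None:
        unknown = donor_mol.eplet_set - set(registry.eplets)
        if unknown:
            raise ContractError(f"molecule carries unknown eplets: {sorted(unknown)}")
    recipient_union: frozenset[str] = frozenset().union(
        *(m.eplet_set for m in recipient_mols)
    ) if recipient_mols else frozenset()
    return MoleculeMismatch(
        donor_mol.molecule_id, donor_mol.kind, donor_mol.eplet_set - recipient_union
    )


def antigen_mismatch(donor: SubjectTyping, recipient: SubjectTyping, locus: str) -> int:
    """Count donor first-field antigen groups at ``locus`` absent from the recipient."""
    if locus not in ("DRB1", "DQB1"):
        raise ContractError(f"antigen mismatch defined for DRB1/DQB1, got {locus}")
    donor_groups = {first_field(c.value) for c in donor.slots[locus]}
    recip_groups = {first_field(c.value) for c in recipient.slots[locus]}
    return len(donor_groups - recip_groups)


def recipient_mismatch_summary(
    donor: SubjectTyping, recipient: SubjectTyping, registry: EpletRegistry
) -> RecipientMismatchSummary:
    """Score every donor molecule against the recipient repertoire.

    Maxima are over donor molecules only; donor null DRB3/4/5 slots
    contribute no molecule and therefore nothing to ``dr_max``.
    """
    donor_mols = enumerate_molecules(donor, registry)
    recip_mols = enumerate_molecules(recipient, registry)
    recip_dr = [m for m in recip_mols if m.kind == "DR_beta"]
    recip_dq = [m for m in recip_mols if m.kind == "DQ_heterodimer"]
    mms: list[MoleculeMismatch] = []
    dr_max = 0
    dq_max = 0
    for mol in donor_mols:
        against = recip_dr if mol.kind == "DR_beta" else recip_dq
        mm = molecule_eplet_mismatch(mol, against)
        mms.append(mm)
        if mol.kind == "DR_beta":
            dr_max = max(dr_max, mm.count)
        else:
            dq_max = max(dq_max, mm.count)
    return RecipientMismatchSummary(
        pair_id=donor.pair_id,
        molecule_mismatches=mms,
        dr_max=dr_max,
        dq_max=dq_max,
        dr_antigen_mm=antigen_mismatch(donor, recipient, "DRB1"),
        dq_antigen_mm=antigen_mismatch(donor, recipient, "DQB1"),
    )


def attribute_dsa_to_molecules(
    dsa_specificity: str,
    donor_mols: list[Molecule],
    allow_serologic: bool = True,
) -> list[str]:
    """Return ids of donor molecules carrying the named specificity.

    Two-field specificities match exactly; one-field (and, when
    ``allow_serologic``, serologic labels like ``DR15``/``DQ5``/``DR52``)
    match by first-field prefix.  Class I / DP specificities return an
    empty list with a warning (third-party antibody, not a class II DSA).
    """
    s = dsa_specificity.strip().upper()
    prefix: str | None = None
    exact: str | None = None
    m = _ALLELE_LIKE_RE.match(s)
    if m is not None:
        locus = m.group(1)
        if locus not in ("DRB1", "DRB3", "DRB4", "DRB5", "DQA1", "DQB1"):
            warnings.warn(
                f"specificity {dsa_specificity!r} is outside HLA-DR/DQ; ignored",
                stacklevel=2,
            )
            return []
        if m.group(3) is not None:
            exact = f"{locus}*{m.group(2)}:{m.group(3)}"
        else:
            prefix = f"{locus}*{m.group(2)}"
    else:
        ms = _SEROLOGIC_RE.match(s)
        if ms is None:
            raise ParseError(f"unparseable DSA specificity: {dsa_specificity!r}")
        if not allow_serologic:
            raise ParseError(
                f"serologic specificity {dsa_specificity!r} rejected by configuration"
            )
        group, num = ms.group(1), ms.group(2)
        if group == "DR" and num in _DR_SEROLOGIC_SPECIAL:
            # DR51/52/53 name whole secondary loci; match any allele there
            prefix = _DR_SEROLOGIC_SPECIAL[num]
        elif group == "DR":
            prefix = f"DRB1*{int(num):02d}"
        else:
            prefix = f"DQB1*{int(num):02d}"
    out = []
    for mol in donor_mols:
        for a in mol.alleles:
            if exact is not None and a == exact:
                out.append(mol.molecule_id)
                break
            if prefix is not None and (
                first_field(a) == prefix or (prefix.endswith("*") and a.startswith(prefix))
            ):
                out.append(mol.molecule_id)
                break
    return out
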