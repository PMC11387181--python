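"""Eplet registries, HLA typing tables, haplotype-frequency tables and
two-field imputation.

The scoring substrate is an :class:`EpletRegistry` mapping two-field HLA
class II alleles (DRB1/3/4/5, DQA1, DQB1) to sets of eplet identifiers.
Subjects are typed with two slots per locus; the two DRB3/4/5 slots are
shared between the three secondary DR loci and may be null (no expressed
gene).  Low-resolution or absent calls are completed against a population
haplotype-frequency table by most-likely (frequency-product argmax)
assignment.  Scorable units are :class:`Molecule` objects: one per DRB
chain allele, and one DQ alpha1-beta1 heterodimer per inherited haplotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    ImputationError,
    ParseError,
    RegistryLookupError,
    ValidationError,
)

CLASS_II_LOCI = ("DRB1", "DRB3", "DRB4", "DRB5", "DQA1", "DQB1")
DR_LOCI = ("DRB1", "DRB3", "DRB4", "DRB5")
DRB345_LOCI = ("DRB3", "DRB4", "DRB5")

#: sentinel population label for the pooled (all-population) frequency table
POOLED = "__pooled__"

_ALLELE_RE = re.compile(r"^(DRB[1345]|DQA1|DQB1)\*([0-9:A-Z]+)$")

TYPING_COLUMNS = [
    "subject_id",
    "role",
    "pair_id",
    "ethnicity",
    "DRB1_1",
    "DRB1_2",
    "DRB345_1",
    "DRB345_2",
    "DQA1_1",
    "DQA1_2",
    "DQB1_1",
    "DQB1_2",
]

FREQUENCY_COLUMNS = ["population", "DRB1", "DRB345", "DQA1", "DQB1", "frequency"]


def normalize_allele(raw: str) -> tuple[str, str, str]:
    """Normalize an allele string to ``(locus, value, resolution)``.

    Values are upper-cased, extra fields beyond two are truncated
    (``DRB1*15:01:01`` -> ``DRB1*15:01``).  A trailing ``N`` expression
    suffix marks a null allele and is only accepted at DRB3/4/5; other
    expression suffixes are rejected.
    """
    s = raw.strip().upper()
    m = _ALLELE_RE.match(s)
    if m is None:
        raise ParseError(f"malformed allele string: {raw!r}")
    locus, rest = m.group(1), m.group(2)
    is_null = False
    if rest and rest[-1].isalpha():
        if rest[-1] == "N":
            is_null = True
            rest = rest[:-1]
        else:
            raise ParseError(
                f"unsupported expression suffix {rest[-1]!r} in allele {raw!r}"
            )
    fields = rest.split(":")
    if not all(f.isdigit() and f for f in fields):
        raise ParseError(f"malformed allele fields in {raw!r}")
    if is_null:
        if locus not in DRB345_LOCI:
            raise ParseError(f"null allele only allowed at DRB3/4/5: {raw!r}")
        return locus, "", "null"
    if len(fields) == 1:
        return locus, f"{locus}*{fields[0]}", "low_res"
    return locus, f"{locus}*{fields[0]}:{fields[1]}", "two_field"


def allele_locus(allele: str) -> str:
    return allele.split("*", 1)[0]


def first_field(allele: str) -> str:
    """``DRB1*15:01`` -> ``DRB1*15`` (antigen-group prefix)."""
    return allele.split(":", 1)[0]


# ---------------------------------------------------------------------------
# Eplet registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Eplet:
    id: str
    locus_class: str  # "DR" | "DQ"
    chain: str  # "alpha" | "beta"
    name: str = ""

    def __post_init__(self):
        if self.locus_class not in ("DR", "DQ"):
            raise ValidationError(f"bad locus_class {self.locus_class!r}")
        if self.chain not in ("alpha", "beta"):
            raise ValidationError(f"bad chain {self.chain!r}")
        if self.locus_class == "DR" and self.chain != "beta":
            raise ValidationError(f"DR eplet {self.id} must be beta-chain")


def _expected_class_chain(locus: str) -> tuple[str, str]:
    if locus in DR_LOCI:
        return "DR", "beta"
    if locus == "DQA1":
        return "DQ", "alpha"
    return "DQ", "beta"


class EpletRegistry:
    """Mapping from two-field alleles to eplet-id sets, with a typed catalog.

    Invariants enforced at construction: every referenced eplet id exists
    in the catalog; DRB alleles carry only DR/beta eplets, DQA1 only
    DQ/alpha, DQB1 only DQ/beta.
    """

    def __init__(
        self,
        allele_to_eplets: Mapping[str, Iterable[str]],
        eplets: Mapping[str, Eplet] | None = None,
    ):
        self.allele_to_eplets: dict[str, frozenset[str]] = {}
        for raw, ids in allele_to_eplets.items():
            locus, value, res = normalize_allele(raw)
            if res != "two_field":
                raise ParseError(f"registry allele must be two-field: {raw!r}")
            self.allele_to_eplets[value] = frozenset(ids)
        if eplets is None:
            eplets = self._infer_catalog()
        self.eplets: dict[str, Eplet] = dict(eplets)
        self._validate()

    def _infer_catalog(self) -> dict[str, Eplet]:
        catalog: dict[str, Eplet] = {}
        for allele, ids in self.allele_to_eplets.items():
            cls, chain = _expected_class_chain(allele_locus(allele))
            for eid in ids:
                prev = catalog.get(eid)
                if prev is not None and (prev.locus_class, prev.chain) != (cls, chain):
                    raise ValidationError(
                        f"eplet {eid} assigned to conflicting locus classes "
                        f"({prev.locus_class}/{prev.chain} vs {cls}/{chain})"
                    )
                catalog[eid] = Eplet(eid, cls, chain, eid)
        return catalog

    def _validate(self) -> None:
        for allele, ids in self.allele_to_eplets.items():
            cls, chain = _expected_class_chain(allele_locus(allele))
            for eid in ids:
                ep = self.eplets.get(eid)
                if ep is None:
                    raise ValidationError(
                        f"allele {allele} references unknown eplet {eid}"
                    )
                if (ep.locus_class, ep.chain) != (cls, chain):
                    raise ValidationError(
                        f"allele {allele} carries eplet {eid} of class "
                        f"{ep.locus_class}/{ep.chain}, expected {cls}/{chain}"
                    )

    def eplet_set(self, allele: str) -> frozenset[str]:
        try:
            return self.allele_to_eplets[allele]
        except KeyError:
            raise RegistryLookupError(f"allele not in registry: {allele}") from None

    def alleles(self, locus: str | None = None) -> list[str]:
        out = sorted(self.allele_to_eplets)
        if locus is not None:
            out = [a for a in out if allele_locus(a) == locus]
        return out

    def to_tsv(self, path) -> None:
        rows = []
        for allele in sorted(self.allele_to_eplets):
            cls, _ = _expected_class_chain(allele_locus(allele))
            ids = ";".join(sorted(self.allele_to_eplets[allele]))
            rows.append({"allele": allele, "locus_class": cls, "eplets": ids})
        pd.DataFrame(rows, columns=["allele", "locus_class", "eplets"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "EpletRegistry":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = {"allele", "eplets"} - set(df.columns)
        if missing:
            raise ParseError(f"registry missing columns: {sorted(missing)}")
        mapping: dict[str, set[str]] = {}
        for i, row in df.iterrows():
            try:
                _, value, res = normalize_allele(row["allele"])
                if res != "two_field":
                    raise ParseError("registry allele must be two-field")
            except ParseError as e:
                raise ParseError(f"registry row {i}: {e}") from None
            ids = {x for x in str(row["eplets"]).split(";") if x}
            mapping[value] = ids
        return cls(mapping)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EpletRegistry)
            and self.allele_to_eplets == other.allele_to_eplets
            and self.eplets == other.eplets
        )


def load_eplet_registry(path) -> EpletRegistry:
    """Load and validate a registry TSV (columns: allele, locus_class, eplets)."""
    return EpletRegistry.from_tsv(path)


# ---------------------------------------------------------------------------
# Subject typing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleCall:
    locus: str  # DRB1 | DRB3 | DRB4 | DRB5 | DRB345 (null slot) | DQA1 | DQB1
    value: str  # normalized allele string; "" for null/absent
    resolution: str  # two_field | low_res | null | absent

    def __post_init__(self):
        if self.resolution not in ("two_field", "low_res", "null", "absent"):
            raise ValidationError(f"bad resolution {self.resolution!r}")
        if self.resolution == "null" and self.locus not in DRB345_LOCI + ("DRB345",):
            raise ValidationError(f"null call only allowed at DRB3/4/5, got {self.locus}")


def _parse_cell(locus_slot: str, cell: str) -> AlleleCall:
    cell = cell.strip()
    if cell == "":
        if locus_slot == "DRB345":
            return AlleleCall("DRB345", "", "null")
        return AlleleCall(locus_slot, "", "absent")
    locus, value, res = normalize_allele(cell)
    if locus_slot == "DRB345":
        if locus not in DRB345_LOCI:
            raise ParseError(f"allele {cell!r} is not a DRB3/4/5 allele")
        if res == "null":
            return AlleleCall(locus, "", "null")
        return AlleleCall(locus, value, res)
    if locus != locus_slot:
        raise ParseError(f"allele {cell!r} found in {locus_slot} column")
    return AlleleCall(locus, value, res)


@dataclass
class SubjectTyping:
    """One subject's class II typing: two slots per locus.

    ``slots`` keys are DRB1, DRB345, DQA1, DQB1, each a list of exactly two
    :class:`AlleleCall`.  The DRB345 slots jointly hold the subject's two
    secondary-DR haplotype positions (DRB3/DRB4/DRB5 alleles or nulls).
    Slot index doubles as haplotype index once typing is phased/imputed.
    """

    subject_id: str
    role: str
    pair_id: str
    ethnicity: str
    slots: dict[str, list[AlleleCall]] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ("donor", "recipient"):
            raise ValidationError(f"bad role {self.role!r}")
        for key in ("DRB1", "DRB345", "DQA1", "DQB1"):
            calls = self.slots.get(key)
            if calls is None or len(calls) != 2:
                raise ValidationError(
                    f"{self.subject_id}: exactly 2 {key} slots required"
                )
        n345 = sum(
            1
            for c in self.slots["DRB345"]
            if c.locus in DRB345_LOCI + ("DRB345",)
        )
        if n345 != 2:
            raise ValidationError(
                f"{self.subject_id}: DRB3+DRB4+DRB5+null slot count must be 2"
            )

    @property
    def calls(self) -> list[AlleleCall]:
        out = []
        for key in ("DRB1", "DRB345", "DQA1", "DQB1"):
            out.extend(self.slots[key])
        return out

    def is_fully_typed(self) -> bool:
        for key in ("DRB1", "DQA1", "DQB1"):
            if any(c.resolution != "two_field" for c in self.slots[key]):
                return False
        return all(
            c.resolution in ("two_field", "null") for c in self.slots["DRB345"]
        )

    def to_row(self) -> dict[str, str]:
        row = {
            "subject_id": self.subject_id,
            "role": self.role,
            "pair_id": self.pair_id,
            "ethnicity": self.ethnicity,
        }
        for key, c1, c2 in (
            ("DRB1", "DRB1_1", "DRB1_2"),
            ("DRB345", "DRB345_1", "DRB345_2"),
            ("DQA1", "DQA1_1", "DQA1_2"),
            ("DQB1", "DQB1_1", "DQB1_2"),
        ):
            for col, call in zip((c1, c2), self.slots[key]):
                row[col] = call.value
        return row


def parse_typing_table(path) -> list[SubjectTyping]:
    """Parse a typing CSV into :class:`SubjectTyping` records.

    Blank DRB345 cells are null slots; blank cells at other loci are
    ``absent`` calls flagged for imputation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(TYPING_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"typing table missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            slots = {
                "DRB1": [_parse_cell("DRB1", row["DRB1_1"]), _parse_cell("DRB1", row["DRB1_2"])],
                "DRB345": [
                    _parse_cell("DRB345", row["DRB345_1"]),
                    _parse_cell("DRB345", row["DRB345_2"]),
                ],
                "DQA1": [_parse_cell("DQA1", row["DQA1_1"]), _parse_cell("DQA1", row["DQA1_2"])],
                "DQB1": [_parse_cell("DQB1", row["DQB1_1"]), _parse_cell("DQB1", row["DQB1_2"])],
            }
        except ParseError as e:
            raise ParseError(f"typing row {i} ({row['subject_id']}): {e}") from None
        out.append(
            SubjectTyping(
                subject_id=row["subject_id"],
                role=row["role"],
                pair_id=row["pair_id"],
                ethnicity=row["ethnicity"],
                slots=slots,
            )
        )
    return out


def write_typing_csv(typings: Iterable[SubjectTyping], path) -> None:
    rows = [t.to_row() for t in typings]
    pd.DataFrame(rows, columns=TYPING_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Haplotype frequency table & imputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Haplotype:
    drb1: str
    drb345: str  # "" when the haplotype carries no expressed DRB3/4/5 gene
    dqa1: str
    dqb1: str

    def key(self) -> str:
        return f"{self.drb1}~{self.drb345 or 'NULL'}~{self.dqa1}~{self.dqb1}"


class HaplotypeFrequencyTable:
    """Population-labelled DRB1~DRB345~DQA1~DQB1 haplotype frequencies."""

    def __init__(self, df: pd.DataFrame):
        missing = set(FREQUENCY_COLUMNS) - set(df.columns)
        if missing:
            raise ParseError(f"frequency table missing columns: {sorted(missing)}")
        df = df.copy()
        df["frequency"] = df["frequency"].astype(float)
        if (df["frequency"] < 0).any():
            raise ValidationError("negative haplotype frequency")
        sums = df.groupby("population")["frequency"].sum()
        bad = sums[sums > 1 + 1e-6]
        if len(bad):
            raise ValidationError(
                f"frequencies sum to >1 for population(s): {list(bad.index)}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    def haplotypes(self, population: str) -> list[tuple[Haplotype, float]]:
        if population == POOLED:
            grp = (
                self.df.groupby(["DRB1", "DRB345", "DQA1", "DQB1"])["frequency"]
                .mean()
                .reset_index()
            )
            rows = grp.itertuples(index=False)
            return [
                (Haplotype(r.DRB1, r.DRB345, r.DQA1, r.DQB1), float(r.frequency))
                for r in rows
            ]
        sub = self.df[self.df["population"] == population]
        return [
            (
                Haplotype(r.DRB1, r.DRB345, r.DQA1, r.DQB1),
                float(r.frequency),
            )
            for r in sub.itertuples(index=False)
        ]

    def to_csv(self, path) -> None:
        self.df[FREQUENCY_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HaplotypeFrequencyTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HaplotypeFrequencyTable):
            return NotImplemented
        a = self.df[FREQUENCY_COLUMNS].sort_values(FREQUENCY_COLUMNS[:-1]).reset_index(drop=True)
        b = other.df[FREQUENCY_COLUMNS].sort_values(FREQUENCY_COLUMNS[:-1]).reset_index(drop=True)
        if not a[FREQUENCY_COLUMNS[:-1]].equals(b[FREQUENCY_COLUMNS[:-1]]):
            return False
        return (a["frequency"].astype(float) - b["frequency"].astype(float)).abs().max() < 1e-12


def _call_matches(call: AlleleCall, hap_allele: str) -> bool:
    if call.resolution == "absent":
        return True
    if call.resolution == "null":
        return hap_allele == ""
    if hap_allele == "":
        return False
    if call.resolution == "two_field":
        return call.value == hap_allele
    # low_res: antigen-group prefix match, locus included in the prefix
    return first_field(hap_allele) == call.value


def _pair_matches(c1: AlleleCall, c2: AlleleCall, a1: str, a2: str) -> bool:
    return (_call_matches(c1, a1) and _call_matches(c2, a2)) or (
        _call_matches(c1, a2) and _call_matches(c2, a1)
    )


def _compatible(typing: SubjectTyping, h1: Haplotype, h2: Haplotype) -> bool:
    s = typing.slots
    return (
        _pair_matches(s["DRB1"][0], s["DRB1"][1], h1.drb1, h2.drb1)
        and _pair_matches(s["DRB345"][0], s["DRB345"][1], h1.drb345, h2.drb345)
        and _pair_matches(s["DQA1"][0], s["DQA1"][1], h1.dqa1, h2.dqa1)
        and _pair_matches(s["DQB1"][0], s["DQB1"][1], h1.dqb1, h2.dqb1)
    )


def _hap_call(locus_slot: str, allele: str) -> AlleleCall:
    if locus_slot == "DRB345":
        if allele == "":
            return AlleleCall("DRB345", "", "null")
        return AlleleCall(allele_locus(allele), allele, "two_field")
    return AlleleCall(locus_slot, allele, "two_field")


def impute_two_field(
    typing: SubjectTyping,
    freq: HaplotypeFrequencyTable,
    population: str | None = None,
) -> SubjectTyping:
    """Complete a typing to two-field resolution by most-likely haplotype pair.

    The completion is the genotype-compatible unordered haplotype pair with
    the maximal frequency product; exact frequency ties are broken by the
    lexicographically smallest concatenation of the two haplotype keys.
    Falls back to the pooled table when ``population`` is not present.
    Already fully-typed subjects are returned unchanged (slot order, and
    hence DQ phase, is taken as given).
    """
    if typing.is_fully_typed():
        return typing
    pop = POOLED
    if population is not None and population in freq.populations:
        pop = population
    haps = freq.haplotypes(pop)
    best: tuple[float, str, Haplotype, Haplotype] | None = None
    for i, (h1, f1) in enumerate(haps):
        for h2, f2 in haps[i:]:
            if not _compatible(typing, h1, h2):
                continue
            a, b = sorted((h1, h2), key=lambda h: h.key())
            score = f1 * f2
            key = a.key() + "|" + b.key()
            if best is None or score > best[0] or (score == best[0] and key < best[1]):
                best = (score, key, a, b)
    if best is None:
        unresolved = [
            f"{c.locus}={c.value or c.resolution}"
            for c in typing.calls
            if c.resolution in ("low_res", "absent")
        ]
        raise ImputationError(
            f"{typing.subject_id}: no compatible haplotype pair in population "
            f"{pop!r} for calls [{', '.join(unresolved)}]"
        )
    _, _, h1, h2 = best
    slots = {
        "DRB1": [_hap_call("DRB1", h1.drb1), _hap_call("DRB1", h2.drb1)],
        "DRB345": [_hap_call("DRB345", h1.drb345), _hap_call("DRB345", h2.drb345)],
        "DQA1": [_hap_call("DQA1", h1.dqa1), _hap_call("DQA1", h2.dqa1)],
        "DQB1": [_hap_call("DQB1", h1.dqb1), _hap_call("DQB1", h2.dqb1)],
    }
    return replace(typing, slots=slots)


# ---------------------------------------------------------------------------
# Molecules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Molecule:
    """A scorable donor/recipient unit.

    ``DR_beta``: a single DRB1/3/4/5 chain allele.  ``DQ_heterodimer``: the
    (DQA1, DQB1) pair inherited on one haplotype, scored as one unit with
    the union of both chains' eplets.
    """

    molecule_id: str
    kind: str  # "DR_beta" | "DQ_heterodimer"
    locus: str  # DRB1 | DRB3 | DRB4 | DRB5 | DQ
    alleles: tuple[str, ...]
    eplet_set: frozenset[str]

    def __post_init__(self):
        if self.kind == "DQ_heterodimer":
            loci = sorted(allele_locus(a) for a in self.alleles)
            if loci != ["DQA1", "DQB1"]:
                raise ValidationError(
                    f"DQ heterodimer needs one DQA1 and one DQB1 allele, got {self.alleles}"
                )
        elif self.kind == "DR_beta":
            if len(self.alleles) != 1 or allele_locus(self.alleles[0]) not in DR_LOCI:
                raise ValidationError(f"DR_beta molecule needs one DRB allele")
        else:
            raise ValidationError(f"bad molecule kind {self.kind!r}")


def enumerate_molecules(typing: SubjectTyping, registry: EpletRegistry) -> list[Molecule]:
    """Enumerate the subject's scorable molecules.

    Exactly two DRB1 molecules (homozygotes contribute two identical ones),
    zero to two DRB3/4/5 molecules (null slots contribute none), and exactly
    two DQ heterodimers, pairing DQA1 and DQB1 by haplotype slot index.
    """
    if not typing.is_fully_typed():
        raise ValidationError(
            f"{typing.subject_id}: typing must be two-field before enumeration"
        )
    sid = typing.subject_id
    mols: list[Molecule] = []
    for i, call in enumerate(typing.slots["DRB1"], start=1):
        mols.append(
            Molecule(
                f"{sid}:DRB1.{i}", "DR_beta", "DRB1", (call.value,),
                registry.eplet_set(call.value),
            )
        )
    for i, call in enumerate(typing.slots["DRB345"], start=1):
        if call.resolution == "null":
            continue
        mols.append(
            Molecule(
                f"{sid}:{call.locus}.{i}", "DR_beta", call.locus, (call.value,),
                registry.eplet_set(call.value),
            )
        )
    for i in (1, 2):
        a = typing.slots["DQA1"][i - 1].value
        b = typing.slots["DQB1"][i - 1].value
        mols.append(
            Molecule(
                f"{sid}:DQ.{i}", "DQ_heterodimer", "DQ", (a, b),
                registry.eplet_set(a) | registry.eplet_set(b),
            )
        )
    return mols
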