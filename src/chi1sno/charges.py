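"""Discrete protonation/charge schemes for pH-dependent MD setups.

Models the manual charge assignment used to emulate pH in classical MD of a
cysteine protease: at pH 7 Asp/Glu are deprotonated (-1), His neutral and
Lys/Arg protonated (+1); at strongly acidic pH ("pH 2 all") Asp/Glu are
neutralized and His carries +1; the "pH 2 his" scheme protonates only the
catalytic histidine and leaves everything else in its pH 7 state.  Termini,
cysteines (including the catalytic thiol, which stays protonated and
neutral) and all non-titratable residues contribute zero in every scheme, so
net charges match the integer totals such setups report.

No pKa prediction or fractional (Henderson-Hasselbalch) charges: schemes
are discrete assignments by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

__all__ = [
    "ProteinSequence",
    "Mutation",
    "ChargeScheme",
    "SCHEMES",
    "scheme_by_name",
    "read_fasta",
    "load_packaged_sequence",
    "count_ionizables",
    "net_charge",
    "apply_mutation",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
IONIZABLE = ("D", "E", "H", "K", "R")

#: Precursor-numbered position of the catalytic histidine.
CATALYTIC_HIS = 275


class ChargeError(ValueError):
    """Inconsistent scheme, sequence or mutation."""


@dataclass(frozen=True)
class ProteinSequence:
    """A mature protein chain with precursor numbering.

    ``numbering_offset`` is the count of N-terminal residues (signal peptide
    plus propeptide) removed on maturation, so chain position ``i`` (1-based)
    carries the precursor label ``i + numbering_offset``.
    """

    residues: str
    numbering_offset: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ChargeError(f"non-canonical residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def at_label(self, label: int) -> str:
        """One-letter code at a precursor-numbered position."""
        i = label - self.numbering_offset - 1
        if not 0 <= i < len(self.residues):
            raise ChargeError(f"position {label} outside the chain")
        return self.residues[i]


_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Mutation:
    """A point mutation in ``X###Y`` notation with precursor numbering."""

    wild_type: str
    position: int
    mutant: str

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        m = _MUT_RE.match(text.strip().upper())
        if not m:
            raise ChargeError(f"cannot parse mutation {text!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


@dataclass(frozen=True)
class ChargeScheme:
    """Named per-residue-type integer charges for one pH condition."""

    name: str
    charges: Mapping[str, int]
    his_target: int | None = None

    def charge_of(self, residue: str, label: int | None = None) -> int:
        if self.his_target is not None and residue == "H":
            # his-only scheme: +1 for the target histidine, else pH 7 state
            return 1 if label == self.his_target else self.charges.get("H", 0)
        return self.charges.get(residue, 0)


PH7 = ChargeScheme("pH7", {"D": -1, "E": -1, "H": 0, "K": 1, "R": 1})
PH2_ALL = ChargeScheme("pH2_all", {"D": 0, "E": 0, "H": 1, "K": 1, "R": 1})
PH2_HIS = ChargeScheme(
    "pH2_his", {"D": -1, "E": -1, "H": 0, "K": 1, "R": 1},
    his_target=CATALYTIC_HIS,
)

SCHEMES: dict[str, ChargeScheme] = {s.name: s for s in (PH7, PH2_ALL, PH2_HIS)}


def scheme_by_name(name: str, his_target: int | None = None) -> ChargeScheme:
    try:
        scheme = SCHEMES[name]
    except KeyError:
        raise ChargeError(
            f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}"
        ) from None
    if his_target is not None and scheme.his_target is not None:
        scheme = replace(scheme, his_target=his_target)
    return scheme


def read_fasta(path: str | Path, numbering_offset: int = 0) -> ProteinSequence:
    record = next(SeqIO.parse(str(path), "fasta"))
    return ProteinSequence(
        residues=str(record.seq).upper(),
        numbering_offset=numbering_offset,
        name=record.id,
    )


def load_packaged_sequence() -> ProteinSequence:
    """The packaged mature-chain FASTA fixture.

    A synthetic stand-in chain (see the file header): it reproduces the
    mature cathepsin L ionizable composition (14 Asp, 10 Glu, 2 His, 4 Lys,
    5 Arg) and the catalytic triad positions 138/275/295 under precursor
    numbering with a 115-residue maturation offset, but is not the natural
    sequence.
    """
    ref = resources.files("chi1sno.data") / "tccathl1_mature_synthetic.fasta"
    with resources.as_file(ref) as path:
        return read_fasta(path, numbering_offset=115)


def count_ionizables(seq: ProteinSequence | str) -> dict[str, int]:
    """Counts of the titratable residue types D, E, H, K, R in the chain."""
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    return {aa: residues.count(aa) for aa in IONIZABLE}


def net_charge(
    seq_or_counts: ProteinSequence | Mapping[str, int],
    scheme: ChargeScheme,
) -> int:
    """Net integer protein charge under a scheme.

    Accepts either a sequence (positional, so the his-only scheme can single
    out its target histidine) or a plain type->count mapping, in which case
    a his-target scheme assumes the target is one of the counted histidines.
    """
    if isinstance(seq_or_counts, ProteinSequence):
        seq = seq_or_counts
        if scheme.his_target is not None:
            if seq.at_label(scheme.his_target) != "H":
                raise ChargeError(
                    f"his_target {scheme.his_target} is "
                    f"{seq.at_label(scheme.his_target)!r}, not histidine"
                )
        return sum(
            scheme.charge_of(aa, label=i + seq.numbering_offset + 1)
            for i, aa in enumerate(seq.residues)
        )
    counts = seq_or_counts
    total = sum(scheme.charges.get(aa, 0) * n for aa, n in counts.items())
    if scheme.his_target is not None:
        if counts.get("H", 0) < 1:
            raise ChargeError("his-target scheme needs at least one histidine")
        total += 1  # the single protonated target histidine
    return total


def apply_mutation(seq: ProteinSequence, m: Mutation | str) -> ProteinSequence:
    """Apply a point mutation, checking the wild-type letter first."""
    if isinstance(m, str):
        m = Mutation.parse(m)
    if m.wild_type not in AMINO_ACIDS or m.mutant not in AMINO_ACIDS:
        raise ChargeError(f"non-canonical mutation {m}")
    i = m.position - seq.numbering_offset - 1
    if not 0 <= i < len(seq.residues):
        raise ChargeError(f"mutation {m} outside the chain")
    if seq.residues[i] != m.wild_type:
        raise ChargeError(
            f"mutation {m}: sequence has {seq.residues[i]!r} at "
            f"position {m.position}"
        )
    mutated = seq.residues[:i] + m.mutant + seq.residues[i + 1:]
    suffix = f"_{m}" if seq.name else str(m)
    return ProteinSequence(mutated, seq.numbering_offset, seq.name + suffix)
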