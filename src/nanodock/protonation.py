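"""pH-dependent fractional bead charges.

Side-chain charges follow the Henderson-Hasselbalch equation with model
(sequence-context-free) pKa values: an acid carries -1/(1 + 10^(pKa - pH)),
a base +1/(1 + 10^(pH - pKa)).  The first and last bead of each chain
additionally carry the N- and C-terminus charge.  Fractional (population
average) charges are used because the electrostatic energy is linear in q.

Structure-derived pKa shifts (buried residues, salt bridges) are out of
scope; charges computed externally, e.g. by PropKa, can be applied with
:func:`load_external_charges`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .structures import CGProtein

logger = logging.getLogger(__name__)

__all__ = ["PKaEntry", "PKaTable", "DEFAULT_PKA", "assign_charges", "load_external_charges"]

ACID = "acid"
BASE = "base"


@dataclass(frozen=True)
class PKaEntry:
    pka: float
    kind: str  # "acid" | "base"


@dataclass(frozen=True)
class PKaTable:
    """Model pKa values for ionizable side chains and chain termini."""

    sidechain: dict[str, PKaEntry] = field(default_factory=dict)
    n_term: PKaEntry = PKaEntry(8.0, BASE)
    c_term: PKaEntry = PKaEntry(3.6, ACID)

    def __post_init__(self) -> None:
        required = {"ASP", "GLU", "HIS", "CYS", "TYR", "LYS", "ARG"}
        missing = required - set(self.sidechain)
        if missing:
            raise ValueError(f"pKa table missing ionizable residues: {sorted(missing)}")


DEFAULT_PKA = PKaTable(
    sidechain={
        "ASP": PKaEntry(3.65, ACID),
        "GLU": PKaEntry(4.25, ACID),
        "HIS": PKaEntry(6.0, BASE),
        "CYS": PKaEntry(8.3, ACID),
        "TYR": PKaEntry(10.07, ACID),
        "LYS": PKaEntry(10.53, BASE),
        "ARG": PKaEntry(12.48, BASE),
    }
)


def hh_charge(entry: PKaEntry, ph: float) -> float:
    """Henderson-Hasselbalch fractional charge of one ionizable group."""
    if entry.kind == ACID:
        return -1.0 / (1.0 + 10.0 ** (entry.pka - ph))
    return +1.0 / (1.0 + 10.0 ** (ph - entry.pka))


def assign_charges(protein: CGProtein, ph: float, table: PKaTable = DEFAULT_PKA) -> CGProtein:
    """Return a copy of the protein with per-bead fractional charges at ``ph``."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH out of range: {ph}")
    out = protein.with_positions(protein.positions())
    # first/last bead per chain carry the terminus charge
    first: dict[str, int] = {}
    last: dict[str, int] = {}
    for i, b in enumerate(out.beads):
        first.setdefault(b.chain_id, i)
        last[b.chain_id] = i
    for i, b in enumerate(out.beads):
        entry = table.sidechain.get(b.residue_name)
        q = hh_charge(entry, ph) if entry is not None else 0.0
        if entry is None and b.residue_name not in _KNOWN_NEUTRAL:
            logger.warning("unknown residue %s treated as non-ionizable", b.residue_name)
        if i == first[b.chain_id]:
            q += hh_charge(table.n_term, ph)
        if i == last[b.chain_id]:
            q += hh_charge(table.c_term, ph)
        b.charge = q
    return out


_KNOWN_NEUTRAL = {
    "ALA", "ASN", "GLN", "GLY", "ILE", "LEU", "MET", "PHE", "PRO", "SER", "THR", "TRP", "VAL",
}


def load_external_charges(protein: CGProtein, path) -> CGProtein:
    """Apply charges from a whitespace-delimited file: chain  resSeq  charge.

    Beads not listed keep their current charge.  Lines starting with '#'
    are comments.  A reference to a residue absent from the protein is an
    error (all offenders are listed).
    """
    overrides: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'chain resSeq charge', got {line!r}")
            overrides[(parts[0], int(parts[1]))] = float(parts[2])
    out = protein.with_positions(protein.positions())  # deep-copies beads, keeps charges
    index = {(b.chain_id, b.residue_seq): b for b in out.beads}
    missing = [key for key in overrides if key not in index]
    if missing:
        raise KeyError(f"charge file references residues absent from protein: {sorted(missing)}")
    for key, q in overrides.items():
        index[key].charge = q
    return out
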