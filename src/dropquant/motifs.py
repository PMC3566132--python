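"""PKA consensus-motif classification of phospho-acceptor sites.

The PKA consensus is R(R/K)X(S/T): arginine at P-3, arginine or lysine at
P-2, any residue at P-1, serine or threonine as the acceptor.  Sites with
arginines at BOTH P-2 and P-3 (the RRXS class) bind PKA with higher
affinity — and are phosphorylated more readily — than sites with a single
arginine at either position (e.g. the RKXS class); this distinction
underlies the fast-versus-slow phosphorylation kinetics of the perilipin
1A and HSL PKA sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PhosphoSiteContext:
    """A candidate phospho-site: a sequence and the 0-based acceptor index."""

    sequence: str
    acceptor_index: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.acceptor_index < 3:
            raise ValueError("acceptor_index must be >= 3 to expose the P-3 residue")
        if self.acceptor_index >= len(seq):
            raise ValueError("acceptor_index out of range")
        if seq[self.acceptor_index] not in ("S", "T"):
            raise ValueError(
                f"acceptor residue must be S or T, got {seq[self.acceptor_index]!r}")

    @property
    def p1(self) -> str:
        return self.sequence[self.acceptor_index - 1]

    @property
    def p2(self) -> str:
        return self.sequence[self.acceptor_index - 2]

    @property
    def p3(self) -> str:
        return self.sequence[self.acceptor_index - 3]


@dataclass(frozen=True)
class PkaSiteCall:
    conforms_to_consensus: bool
    arginines_at_p2_p3: int
    predicted_affinity: str  # "high" | "low" | "none"


def classify_pka_site(site: PhosphoSiteContext) -> PkaSiteCall:
    """Classify one acceptor site against the PKA consensus R(R/K)X(S/T).

    Conformance requires R at P-3 and R or K at P-2; predicted affinity is
    "high" with arginines at both P-2 and P-3, "low" with exactly one, and
    "none" with neither.  Only P-2, P-3 and the acceptor influence the call.
    """
    n_arg = int(site.p2 == "R") + int(site.p3 == "R")
    conforms = site.p3 == "R" and site.p2 in ("R", "K")
    affinity = {2: "high", 1: "low", 0: "none"}[n_arg]
    return PkaSiteCall(conforms_to_consensus=conforms,
                       arginines_at_p2_p3=n_arg,
                       predicted_affinity=affinity)


def scan_sequence(sequence: str, name: str = "") -> pd.DataFrame:
    """Score every S/T with at least 3 upstream residues in one sequence."""
    sequence = sequence.upper()
    rows = []
    for i, residue in enumerate(sequence):
        if residue not in ("S", "T") or i < 3:
            continue
        call = classify_pka_site(PhosphoSiteContext(sequence, i))
        rows.append({
            "name": name,
            "position": i + 1,  # 1-based, the field's residue numbering
            "acceptor": residue,
            "p3": sequence[i - 3],
            "p2": sequence[i - 2],
            "p1": sequence[i - 1],
            "conforms_to_consensus": call.conforms_to_consensus,
            "arginines_at_p2_p3": call.arginines_at_p2_p3,
            "predicted_affinity": call.predicted_affinity,
        })
    return pd.DataFrame(rows, columns=[
        "name", "position", "acceptor", "p3", "p2", "p1",
        "conforms_to_consensus", "arginines_at_p2_p3", "predicted_affinity"])


def scan_fasta(path: str | Path) -> pd.DataFrame:
    """Scan every record of a FASTA file for PKA consensus sites."""
    from Bio import SeqIO

    frames = [scan_sequence(str(rec.seq), name=rec.id)
              for rec in SeqIO.parse(str(path), "fasta")]
    if not frames:
        return scan_sequence("")
    return pd.concat(frames, ignore_index=True)
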