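#!/usr/bin/env python
"""Classify PKA phospho-site contexts against the R(R/K)X(S/T) consensus.

The perilipin 1A and HSL PKA-site flanking sequences are not bundled with
the package (supply the full-length proteins as FASTA to scan them); this
driver instead demonstrates the classifier on the canonical context
classes and writes results/motif_classes.csv.  The two-arginine (RRXS)
class is the high-affinity PKA substrate class; a single arginine at
P-2/P-3 (e.g. RKXS) marks lower affinity; no arginine means no consensus.
"""

from pathlib import Path

import pandas as pd

from dropquant.motifs import PhosphoSiteContext, classify_pka_site

OUT = Path(__file__).resolve().parent.parent / "results"

EXAMPLES = {
    "RRXS_class": "LSVRRRSLLE",   # arginines at P-2 and P-3: high affinity
    "RKXS_class": "LSVRKGSLLE",   # single arginine at P-3: low affinity
    "KRXS_class": "LSVKRGSLLE",   # arginine only at P-2: off-consensus
    "no_basic": "LSVAAGSLLE",
}


def main() -> None:
    rows = []
    for name, seq in EXAMPLES.items():
        idx = seq.index("S", 3)
        call = classify_pka_site(PhosphoSiteContext(seq, idx))
        rows.append({"class": name, "context": seq,
                     "p3": seq[idx - 3], "p2": seq[idx - 2],
                     "conforms": call.conforms_to_consensus,
                     "arginines_at_p2_p3": call.arginines_at_p2_p3,
                     "predicted_affinity": call.predicted_affinity})
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "motif_classes.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
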