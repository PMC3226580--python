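"""Classify pathway responsiveness and trace the normalized-pathway-coverage curve.

Counts each pathway's significant responses across the 43 conditions,
computes NPC(theta) for every threshold, and applies the published class
cutoffs: HR at >=10 significant responses, MR at 5-9, LR below 5.
"""

import argparse
import json
from pathlib import Path

from pathwayhubs.enrichment import NESMatrix
from pathwayhubs.io_formats import read_matrix
from pathwayhubs.responsiveness import npc_curve, responsiveness_profile

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    nes = NESMatrix(
        nes=read_matrix(SCRATCH / "nes.tsv"),
        nominal_p=read_matrix(SCRATCH / "nominal_p.tsv"),
    )
    profile = responsiveness_profile(nes)
    curve = npc_curve(profile["n_significant"], len(nes.conditions))

    profile.rename_axis("pathway").to_csv(RESULTS / "responsiveness.tsv", sep="\t")
    curve.to_csv(RESULTS / "npc_curve.tsv", sep="\t", index=False)

    fractions = (profile["class"].value_counts(normalize=True) * 100).round(1)
    summary = {
        "pathways": len(profile),
        "conditions": len(nes.conditions),
        "class_counts": profile["class"].value_counts().to_dict(),
        "class_percent": fractions.to_dict(),
    }
    (RESULTS / "responsiveness_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"classes: {summary['class_counts']} ({summary['class_percent']} %)")
    print(f"wrote {RESULTS/'responsiveness.tsv'}, npc_curve.tsv, responsiveness_summary.json")


if __name__ == "__main__":
    main()
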