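#!/usr/bin/env python
"""Generate the synthetic two-plex TMT experiment with planted truth.

Writes the full input tables (phosphosite table, protein groups, FASTA,
design, kinase-substrate and regulatory-site flat files) to scratch/sim/
and a small summary of what was planted to results/01_simulation_truth.json.
"""

import json
from pathlib import Path

from epiphos.simulate import default_config, generate_experiment, generate_kinase_db

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = default_config()
    exp = generate_experiment(cfg, SEED)
    out = ROOT / "scratch" / "sim"
    paths = exp.write(out)
    ks, reg = generate_kinase_db(cfg, SEED)
    ks.to_csv(out / "kinase_substrates.tsv", sep="\t", index=False)
    reg.to_csv(out / "regulatory_sites.tsv", sep="\t", index=False)

    gt = exp.ground_truth
    summary = {
        "seed": SEED,
        "n_features": cfg.n_features,
        "n_proteins": cfg.n_proteins,
        "n_kinases": cfg.n_kinases,
        "n_phospho_rows": len(exp.phospho_table),
        "planted_effect_sets": [
            {"n": len(e["feature_ids"]), "log2fc": e["log2fc"], "plex": e["plex"]}
            for e in gt["planted_effects"]
        ],
        "planted_kinases": [
            {"kinase": k["kinase"], "log2fc": k["log2fc"], "plex": k["plex"],
             "n_substrates": k["n_substrates"]}
            for k in gt["planted_kinases"]
        ],
        "n_planted_protein_changes": len(gt["planted_proteins"]),
        "n_localization_failures": len(gt["loc_fail_feature_ids"]),
        "n_duplicate_features": len(gt["duplicate_feature_ids"]),
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "01_simulation_truth.json").write_text(
        json.dumps(summary, indent=1) + "\n"
    )
    print(f"wrote inputs to {out}")
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
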