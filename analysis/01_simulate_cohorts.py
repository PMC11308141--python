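#!/usr/bin/env python
"""Simulate a two-cohort microbiome MR study and write its input files.

Draws a screen of 20 synthetic taxa (4 with a true causal effect on the
outcome, log-OR 0.35) against one outcome cohort, with LD blocks,
palindromic variants and allele-orientation flips — the hazards a real
summary-statistics pipeline must survive — then writes the exposure files,
outcome file, LD triplets, ground truth and a ready-to-run YAML config
under results/simulated/.
"""

import dataclasses
import json
from pathlib import Path

import yaml

import micromr as m
from micromr import gwas_io

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    base = dataclasses.replace(
        m.scenario("clean_causal"),
        n_variants=60, n_causal=12, ld_block_size=3,
        frac_palindromic=0.1, frac_flipped=0.3,
    )
    thetas = [0.35] * 4 + [0.0] * 16
    exposures, outcome, ld, truths = m.simulate_screen(20, thetas, base, seed=SEED)

    manifest = []
    for exp in exposures:
        path = OUT / f"{exp.trait_id}_exposure.tsv"
        gwas_io.write_summary_stats(exp, path)
        manifest.append([exp.trait_id, str(path)])
    gwas_io.write_summary_stats(outcome, OUT / "outcome.tsv")
    ld.write_triplets(OUT / "ld_triplets.tsv")
    (OUT / "ground_truth.json").write_text(json.dumps(
        {t: {"theta": tr.theta, "causal_rsids": tr.causal_rsids} for t, tr in truths.items()},
        indent=2) + "\n")

    config = {
        "exposures": manifest,
        "outcome_path": str(OUT / "outcome.tsv"),
        "ld_path": str(OUT / "ld_triplets.tsv"),
        "population": "synthetic_cohort",
        "seed": SEED,
        "out_dir": str(OUT.parent / "screen"),
    }
    (OUT / "run_config.yaml").write_text(yaml.safe_dump(config))
    n_causal_taxa = sum(1 for t in thetas if t != 0)
    print(f"wrote {len(manifest)} exposure files ({n_causal_taxa} truly causal, "
          f"theta=0.35) + outcome + LD to {OUT}")


if __name__ == "__main__":
    main()
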