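"""Invariant-column detection and motif scanning on a simulated family.

The conservation analysis of a real protein family asks two questions:
which alignment columns are invariant (candidate functional residues,
e.g. invariant cysteines that may form disulfide bridges or a
redox/zinc-finger CXXC site), and does a positional motif such as
C-F-[AT]-C-[FY] sit where expected?  Real family alignments live in
public repositories; this driver exercises the identical machinery on a
simulated family in which conservation arises from short branch lengths,
plus a constructed reference sequence with a planted CXXC motif.

Writes results/02_conservation.{json,tsv}.
"""

import argparse
import json
from pathlib import Path

from coevokit.seqcore import (
    MotifPattern,
    Sequence,
    column_conservation,
    invariant_residue_counts,
    scan_motif,
)
from coevokit.synthdata import SimConfig, simulate_panel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # short branches -> realistic mix of invariant and variable columns
    config = SimConfig(n_species=12, seq_length=200, p_dup=0.1, p_loss=0.0,
                       branch_length_mean=0.05, seed=args.seed)
    bundle = simulate_panel(config)
    report = column_conservation(bundle.msa_a)
    inv = invariant_residue_counts(bundle.msa_a)
    n_invariant = int(report.is_invariant.sum())
    print(f"family A alignment: {len(bundle.msa_a)} rows x "
          f"{bundle.msa_a.length} columns, {n_invariant} invariant columns")
    print(f"invariant-residue counts (top): "
          f"{dict(sorted(inv.items(), key=lambda kv: -kv[1])[:5])}")
    print(f"invariant cysteines: {inv.get('C', 0)}")

    # positional motif scanning on a constructed reference sequence with a
    # CF[AT]C[FY] site planted at offset 34 (so it also fits CXXC at 34)
    ref = Sequence(
        "reference", "M" + "A" * 32 + "CFACY" + "G" * 20 + "CAAC" + "W" * 10,
    )
    strict = MotifPattern.from_string("CF[AT]C[FY]", anchor=34)
    fuzzy = MotifPattern.from_string("CXXC")
    hits_strict = scan_motif(ref, strict)
    hits_fuzzy = scan_motif(ref, fuzzy)
    print(f"strict motif CF[AT]C[FY] matches at {hits_strict} "
          f"(anchor 34 hit: {34 in hits_strict})")
    print(f"fuzzy motif CXXC matches at {hits_fuzzy} — the strict site is a "
          "special case of the fuzzy pattern, which also picks up the "
          "second cysteine pair")

    summary = {
        "seed": args.seed,
        "n_rows": len(bundle.msa_a),
        "n_columns": bundle.msa_a.length,
        "n_invariant_columns": n_invariant,
        "invariant_residue_counts": inv,
        "motif_strict_matches": hits_strict,
        "motif_strict_anchor_hit": 34 in hits_strict,
        "motif_fuzzy_matches": hits_fuzzy,
    }
    (args.outdir / "02_conservation.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    report.to_csv(args.outdir / "02_conservation.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
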