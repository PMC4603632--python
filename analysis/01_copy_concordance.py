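"""Copy-number concordance of the two gene families across eight eutherians.

Cross-tabulates the packaged 8-species panel (family A unique in
primates/guinea pig, absent in armadillo, duplicated in mouse, rat and
cow; family B single-copy except the same three duplicated species),
tests independence with Pearson's chi-squared, and compares the
asymptotic p-value with the exact and Monte-Carlo permutation versions
— several expected counts are below 5, so the permutation companion is
the sounder reference.

Writes results/01_copy_concordance.json and .tsv.
"""

import argparse
import json
from pathlib import Path

from coevokit import packaged_copy_panel_path
from coevokit.coevo import (
    contingency_from_profiles,
    exact_permutation_independence_test,
    pearson_chi2_test,
    permutation_independence_test,
    read_copy_profiles,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    profiles = read_copy_profiles(packaged_copy_panel_path())
    table = contingency_from_profiles(profiles)
    chi2 = pearson_chi2_test(table)
    exact = exact_permutation_independence_test(profiles)
    mc = permutation_independence_test(profiles, n_perm=100_000, seed=args.seed)

    print("contingency table (rows: family B copies, cols: family A copies)")
    print(table.to_frame().to_string())
    print(f"\nasymptotic chi2 = {chi2.statistic:.4f}, df = {chi2.df}, "
          f"p = {chi2.p_value:.4f}")
    print(f"exact permutation p = {exact.p_value:.4f} "
          f"({exact.n_permutations} distinguishable orderings)")
    print(f"Monte-Carlo permutation p = {mc.p_value:.4f} "
          f"({mc.n_permutations} permutations, seed {args.seed})")
    print("\nThe copy numbers of the two families are dependent at the 5 % "
          "level under all three computations: concordant duplication "
          "histories, i.e. co-evolution.")

    summary = {
        "panel": [p.species for p in profiles],
        "counts": table.counts.tolist(),
        "row_levels_copies_b": list(table.row_labels),
        "col_levels_copies_a": list(table.col_labels),
        "asymptotic": {"statistic": chi2.statistic, "df": chi2.df,
                       "p_value": chi2.p_value},
        "exact_permutation": {"p_value": exact.p_value,
                              "n_permutations": exact.n_permutations},
        "monte_carlo_permutation": {"p_value": mc.p_value,
                                    "n_permutations": mc.n_permutations,
                                    "seed": args.seed},
    }
    (args.outdir / "01_copy_concordance.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    table.to_frame().to_csv(args.outdir / "01_copy_concordance.tsv", sep="\t")


if __name__ == "__main__":
    main()
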