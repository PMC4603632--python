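"""Co-evolution statistics for two gene families across a species panel.

Three lines of evidence that two families share an evolutionary history:

1. **Copy-number concordance** — are the per-species copy numbers of the
   two families statistically dependent?  A contingency table of species
   counts by (family A copies, family B copies) is tested with Pearson's
   chi-squared; a permutation companion is provided for the small panels
   typical of this kind of study, where several expected counts fall
   below 5 and the asymptotic reference distribution is shaky.

2. **Identity-vector correlation** — percent identity of every species'
   protein to a reference species (human, say), computed inside each
   family's alignment; Pearson correlation of the two per-species
   vectors.

3. **Mirror-tree correlation** — Pearson correlation of the two
   families' inter-species distance matrices over their common species,
   taken over upper-triangle entries, with a label-permutation null for
   the p-value.  High correlation of the distance matrices means the two
   family trees mirror each other.

Permutation p-values use the add-one estimator
``(1 + #{null >= observed}) / (1 + n_perm)`` and an explicit seed; exact
enumeration over all distinguishable permutations is available (and used
automatically by the tests) when that number is small.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from sympy.utilities.iterables import multiset_permutations

from .seqcore import GAP, MSA

__all__ = [
    "CopyProfile",
    "ContingencyTable",
    "IndependenceTestResult",
    "DistanceMatrix",
    "CorrelationResult",
    "read_copy_profiles",
    "contingency_from_profiles",
    "pearson_chi2_test",
    "permutation_independence_test",
    "exact_permutation_independence_test",
    "n_distinguishable_permutations",
    "pairwise_identity",
    "identity_vector",
    "vector_correlation",
    "msa_distance_matrix",
    "mirror_correlation",
    "mirror_permutation_pvalue",
    "exact_mirror_permutation_pvalue",
]

logger = logging.getLogger(__name__)

MAX_COPIES_DEFAULT = 10


@dataclass(frozen=True)
class CopyProfile:
    """Copy numbers of the two families in one species."""

    species: str
    copies_a: int
    copies_b: int
    complete_genome: bool = False

    def __post_init__(self):
        for v in (self.copies_a, self.copies_b):
            if not (0 <= v <= MAX_COPIES_DEFAULT):
                raise ValueError(
                    f"{self.species}: copy number {v} outside "
                    f"[0, {MAX_COPIES_DEFAULT}]"
                )


def read_copy_profiles(path: str | Path) -> list[CopyProfile]:
    """TSV columns: species, copies_a, copies_b[, complete_genome]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for rec in df.itertuples(index=False):
        profiles.append(
            CopyProfile(
                species=str(rec.species),
                copies_a=int(rec.copies_a),
                copies_b=int(rec.copies_b),
                complete_genome=bool(getattr(rec, "complete_genome", False)),
            )
        )
    if len({p.species for p in profiles}) != len(profiles):
        raise ValueError(f"{path}: duplicate species in panel")
    return profiles


@dataclass(frozen=True)
class ContingencyTable:
    """Species counts cross-classified by copy number of each family.

    Rows are family-B copy levels, columns family-A copy levels (the
    conventional orientation for this kind of panel); levels are the
    observed distinct values in ascending order, so no all-zero row or
    column can occur.
    """

    row_labels: tuple[int, ...]  # copies_b levels
    col_labels: tuple[int, ...]  # copies_a levels
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def degenerate(self) -> bool:
        return self.shape[0] < 2 or self.shape[1] < 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"b={r}" for r in self.row_labels],
            columns=[f"a={c}" for c in self.col_labels],
        )


@dataclass(frozen=True)
class IndependenceTestResult:
    statistic: float
    df: int
    p_value: float
    method: str  # "asymptotic" | "permutation" | "exact-permutation"
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_pairs: int
    p_value: float | None = None
    common_labels: tuple[str, ...] = ()
    method: str = "pearson"
    n_permutations: int | None = None
    seed: int | None = None


def contingency_from_profiles(profiles: list[CopyProfile]) -> ContingencyTable:
    """Cross-tabulate the panel by (copies_b, copies_a)."""
    if not profiles:
        raise ValueError("empty species panel")
    a = np.array([p.copies_a for p in profiles])
    b = np.array([p.copies_b for p in profiles])
    col_labels = tuple(sorted(set(a.tolist())))
    row_labels = tuple(sorted(set(b.tolist())))
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for ai, bi in zip(a, b):
        counts[row_labels.index(bi), col_labels.index(ai)] += 1
    table = ContingencyTable(row_labels, col_labels, counts)
    if table.degenerate:
        logger.warning(
            "degenerate %dx%d contingency table (panel has a constant "
            "copy number); independence is untestable", *table.shape
        )
    return table


def _chi2_statistic(counts: np.ndarray) -> float:
    """Pearson chi-squared statistic, no continuity correction."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (counts - expected) ** 2 / expected
    return float(np.nansum(terms))


def pearson_chi2_test(table: ContingencyTable) -> IndependenceTestResult:
    """Asymptotic Pearson chi-squared independence test.

    ``statistic = sum (O - E)^2 / E`` with expectations from the row and
    column marginals, ``df = (r - 1)(c - 1)``, and the p-value from the
    upper tail of the chi-squared distribution via the regularized
    (upper) incomplete gamma function.  No continuity correction.

    Note several expected counts are typically < 5 on small species
    panels; see :func:`permutation_independence_test` for an exact-style
    companion that does not rely on the asymptotic reference.
    """
    if table.degenerate:
        raise ValueError(
            "contingency table is degenerate (single row or column); "
            "the asymptotic test is undefined — use the permutation test"
        )
    statistic = _chi2_statistic(table.counts)
    r, c = table.shape
    df = (r - 1) * (c - 1)
    p_value = float(special.gammaincc(df / 2.0, statistic / 2.0))
    return IndependenceTestResult(statistic, df, p_value, "asymptotic")


def n_distinguishable_permutations(values: list[int]) -> int:
    """Number of distinct orderings of a multiset (n! over level counts)."""
    total = math.factorial(len(values))
    for count in pd.Series(values).value_counts():
        total //= math.factorial(int(count))
    return total


def _permuted_statistics(a: np.ndarray, b_perms: np.ndarray) -> np.ndarray:
    """Chi-squared statistic for each permuted copies_b row of ``b_perms``."""
    a_levels, a_idx = np.unique(a, return_inverse=True)
    out = np.empty(len(b_perms))
    for i, b in enumerate(b_perms):
        b_levels, b_idx = np.unique(b, return_inverse=True)
        counts = np.zeros((len(b_levels), len(a_levels)))
        np.add.at(counts, (b_idx, a_idx), 1.0)
        out[i] = _chi2_statistic(counts)
    return out


def permutation_independence_test(
    profiles: list[CopyProfile], n_perm: int = 9999, seed: int | None = None
) -> IndependenceTestResult:
    """Monte-Carlo permutation test of copy-number independence.

    Shuffles the family-B column against family A; the statistic is the
    Pearson chi-squared value of the re-tabulated panel, and
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.  Valid at any table
    size, unlike the asymptotic test.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("permutation test requires an explicit seed")
    a = np.array([p.copies_a for p in profiles])
    b = np.array([p.copies_b for p in profiles])
    observed = _chi2_statistic(contingency_from_profiles(profiles).counts)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(b, (n_perm, 1)), axis=1)
    null = _permuted_statistics(a, perms)
    hits = int(np.sum(null >= observed - 1e-12))
    p = (1 + hits) / (1 + n_perm)
    df = (len(set(b.tolist())) - 1) * (len(set(a.tolist())) - 1)
    return IndependenceTestResult(
        observed, df, p, "permutation", n_permutations=n_perm, seed=seed
    )


def exact_permutation_independence_test(
    profiles: list[CopyProfile], limit: int = 100_000
) -> IndependenceTestResult:
    """Exact permutation p-value by full enumeration.

    Enumerates every distinguishable ordering of the family-B copy
    multiset against the fixed family-A column;
    ``p = #{perm >= obs} / #perms`` (the identity ordering is in the
    enumeration, so p > 0).  Refuses panels with more than ``limit``
    distinguishable orderings.
    """
    a = np.array([p.copies_a for p in profiles])
    b = [p.copies_b for p in profiles]
    n_total = n_distinguishable_permutations(b)
    if n_total > limit:
        raise ValueError(
            f"{n_total} distinguishable permutations exceeds limit {limit}; "
            "use the Monte-Carlo test"
        )
    observed = _chi2_statistic(contingency_from_profiles(profiles).counts)
    perms = np.array(list(multiset_permutations(b)))
    null = _permuted_statistics(a, perms)
    hits = int(np.sum(null >= observed - 1e-12))
    df = (len(set(b)) - 1) * (len(set(a.tolist())) - 1)
    return IndependenceTestResult(
        observed, df, hits / n_total, "exact-permutation", n_permutations=n_total
    )


# ---------------------------------------------------------------------------
# Identity vectors


def pairwise_identity(gapped_a: str, gapped_b: str) -> float:
    """Percent identity of two rows of one alignment.

    Columns where both rows are gaps are excluded; columns where exactly
    one row is a gap count as mismatches.  Deterministic — no
    realignment.
    """
    pairs = [(x, y) for x, y in zip(gapped_a, gapped_b) if (x, y) != (GAP, GAP)]
    if not pairs:
        return 0.0
    matches = sum(1 for x, y in pairs if x == y and x != GAP)
    return 100.0 * matches / len(pairs)


def identity_vector(msa: MSA, reference_species: str) -> dict[str, float]:
    """Percent identity of every other species to a reference species.

    Species with several rows (paralogs) are collapsed by the **maximum**
    identity over row pairs, so each species contributes its closest
    paralog to the reference.
    """
    ref_rows = [r for r in msa.rows if r.species == reference_species]
    if not ref_rows:
        raise KeyError(
            f"reference species {reference_species!r} not in MSA; available: "
            f"{sorted(set(msa.species))}"
        )
    out: dict[str, float] = {}
    for row in msa.rows:
        if row.species == reference_species:
            continue
        ident = max(pairwise_identity(ref.gapped, row.gapped) for ref in ref_rows)
        if row.species in out:
            logger.info("species %s has multiple rows; keeping max identity",
                        row.species)
        out[row.species] = max(ident, out.get(row.species, -1.0))
    return out


def vector_correlation(
    va: dict[str, float], vb: dict[str, float]
) -> CorrelationResult:
    """Pearson correlation of two per-species vectors over shared species."""
    common = sorted(set(va) & set(vb))
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 shared species, got {len(common)}: {common}"
        )
    x = np.array([va[s] for s in common])
    y = np.array([vb[s] for s in common])
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n_pairs=len(common), common_labels=tuple(common))


# ---------------------------------------------------------------------------
# Mirror-tree


class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels")
        if values.shape != (len(labels), len(labels)):
            raise ValueError("shape mismatch")
        if not np.allclose(values, values.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(values), 0):
            raise ValueError("diagonal not zero")
        if (values < -1e-9).any():
            raise ValueError("negative distances")
        self.labels = list(labels)
        self.values = values

    def __len__(self) -> int:
        return len(self.labels)

    def restrict(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def relabelled(self, mapping: dict[str, str]) -> "DistanceMatrix":
        return DistanceMatrix([mapping.get(l, l) for l in self.labels], self.values)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_newick(cls, path_or_string: str | Path) -> "DistanceMatrix":
        """Patristic distances between the leaves of a newick tree."""
        import dendropy

        text = str(path_or_string)
        if "(" not in text:
            text = Path(path_or_string).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        values = np.array(
            [[0.0 if t1 is t2 else pdm.patristic_distance(t1, t2) for t2 in taxa]
             for t1 in taxa]
        )
        return cls(labels, values)


def msa_distance_matrix(msa: MSA) -> DistanceMatrix:
    """Per-species distance matrix, ``distance = 100 - identity_pct``.

    Species with several paralog rows are collapsed by the **mean**
    distance over row pairs (logged); the diagonal is forced to zero.
    """
    if len(msa) < 3:
        raise ValueError("need >= 3 rows")
    species = sorted(set(msa.species))
    by_sp = {s: [r for r in msa.rows if r.species == s] for s in species}
    multi = [s for s, rows in by_sp.items() if len(rows) > 1]
    if multi:
        logger.info("collapsing multi-paralog species by mean distance: %s", multi)
    k = len(species)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dists = [
                100.0 - pairwise_identity(ra.gapped, rb.gapped)
                for ra in by_sp[species[i]]
                for rb in by_sp[species[j]]
            ]
            values[i, j] = values[j, i] = float(np.mean(dists))
    return DistanceMatrix(species, values)


def mirror_correlation(da: DistanceMatrix, db: DistanceMatrix) -> CorrelationResult:
    """Mirror-tree statistic: Pearson r of the two matrices' upper
    triangles over their common labels (sorted for label-order
    invariance)."""
    common = sorted(set(da.labels) & set(db.labels))
    if len(common) < 4:
        raise ValueError(f"need >= 4 common labels, got {len(common)}: {common}")
    xa = da.restrict(common).upper_triangle()
    xb = db.restrict(common).upper_triangle()
    r = float(stats.pearsonr(xa, xb).statistic)
    k = len(common)
    return CorrelationResult(r=r, n_pairs=k * (k - 1) // 2,
                             common_labels=tuple(common))


def _mirror_null_r(
    da: DistanceMatrix, db: DistanceMatrix, perm_labels: list[str]
) -> float:
    """r after reassigning db's labels according to ``perm_labels``."""
    mapping = dict(zip(db.labels, perm_labels))
    return mirror_correlation(da, db.relabelled(mapping)).r


def mirror_permutation_pvalue(
    da: DistanceMatrix,
    db: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> CorrelationResult:
    """Permutation p-value for the mirror-tree correlation.

    The null shuffles the species-label assignment of the second matrix
    before restriction to common labels, breaking any shared tree
    structure while preserving both distance distributions.  Two-sided
    by default (``|r_perm| >= |r_obs|``); ``alternative="greater"`` for
    the one-sided version.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("permutation test requires an explicit seed")
    obs = mirror_correlation(da, db)
    rng = np.random.default_rng(seed)
    labels = np.array(db.labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        r = _mirror_null_r(da, db, perm.tolist())
        if alternative == "two-sided":
            hits += abs(r) >= abs(obs.r) - 1e-12
        else:
            hits += r >= obs.r - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return CorrelationResult(
        r=obs.r, n_pairs=obs.n_pairs, p_value=p, common_labels=obs.common_labels,
        n_permutations=n_perm, seed=seed,
    )


def exact_mirror_permutation_pvalue(
    da: DistanceMatrix,
    db: DistanceMatrix,
    alternative: str = "two-sided",
    limit: int = 100_000,
) -> CorrelationResult:
    """Exact p-value enumerating all label permutations of db.

    ``p = #{perm with |r| >= |r_obs|} / k!`` (identity included).  Only
    for small label sets — k! grows fast.
    """
    k = len(db.labels)
    if math.factorial(k) > limit:
        raise ValueError(f"{k}! permutations exceed limit {limit}")
    obs = mirror_correlation(da, db)
    hits = total = 0
    for perm in itertools.permutations(db.labels):
        r = _mirror_null_r(da, db, list(perm))
        if alternative == "two-sided":
            hits += abs(r) >= abs(obs.r) - 1e-12
        else:
            hits += r >= obs.r - 1e-12
        total += 1
    return CorrelationResult(
        r=obs.r, n_pairs=obs.n_pairs, p_value=hits / total,
        common_labels=obs.common_labels, n_permutations=total,
    )
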