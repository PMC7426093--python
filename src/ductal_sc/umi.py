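"""UMI sequencing-error correction.

Single-base sequencing errors in the UMI turn one true molecule into a
spurious extra UMI that is (a) observed in very few reads and (b) one
substitution away from the true UMI.  The correction is therefore:

1. discard reads whose UMI contains an undetermined base (``N``);
2. within each (cell barcode, gene) group, merge every UMI seen exactly
   once into a hamming-distance-1 neighbor that is supported by two or
   more reads, adding its read to the recipient.

Multiply-observed UMIs are never merged, and singletons without a
qualifying neighbor are kept.  When a singleton has several qualifying
neighbors, the one with the most reads wins; remaining ties go to the
lexicographically smallest UMI.  Merging is a single pass over the initial
table state: read counts augmented during the pass do not recruit further
singletons, which makes the result independent of iteration order.

A read table is a :class:`pandas.DataFrame` with columns
``barcode, gene, umi, reads`` and unique (barcode, gene, umi) rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CountMatrix

READ_TABLE_COLUMNS = ["barcode", "gene", "umi", "reads"]

_DNA = "ACGT"


def _check_read_table(reads: pd.DataFrame) -> None:
    missing = [c for c in READ_TABLE_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")


def drop_n_umis(reads: pd.DataFrame) -> pd.DataFrame:
    """Remove records whose UMI contains an ``N`` base."""
    _check_read_table(reads)
    if len(reads) == 0:
        return reads.copy()
    keep = ~reads["umi"].str.contains("N", regex=False)
    return reads.loc[keep].reset_index(drop=True)


def _substitution_neighbors(umi: str):
    """All 3L strings at hamming distance exactly 1 from ``umi``."""
    for pos, base in enumerate(umi):
        for alt in _DNA:
            if alt != base:
                yield umi[:pos] + alt + umi[pos + 1:]


def _collapse_group(umis: np.ndarray, reads: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse one (barcode, gene) group; returns surviving (umis, reads).

    Candidate recipients are found by enumerating the 3L single-substitution
    variants of each singleton and looking them up in a hash of the
    multi-read UMIs, which is O(n.L) instead of O(n^2) pairwise.
    """
    multi = {u: r for u, r in zip(umis, reads) if r >= 2}
    if not multi:
        return umis, reads
    out_reads = dict(zip(umis, reads))
    for u, r in zip(umis, reads):
        if r != 1:
            continue
        best = None
        for cand in _substitution_neighbors(u):
            cr = multi.get(cand)
            if cr is None:
                continue
            # highest initial read count, then lexicographically smallest
            if best is None or (cr, _rev(cand)) > (best[1], _rev(best[0])):
                best = (cand, cr)
        if best is not None:
            out_reads[best[0]] += 1
            del out_reads[u]
    surv = sorted(out_reads)
    return np.asarray(surv, dtype=object), np.asarray(
        [out_reads[u] for u in surv], dtype=np.int64)


class _rev(str):
    """Reverse string ordering, so max() prefers the smallest UMI on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def collapse_umis(reads: pd.DataFrame) -> pd.DataFrame:
    """Merge hamming-1 singleton UMIs into multiply-observed neighbors.

    Operates independently within each (barcode, gene) group.  Total reads
    are conserved; the distinct-UMI count per group never increases.
    """
    _check_read_table(reads)
    if len(reads) == 0:
        return reads.copy()
    lengths = reads["umi"].str.len().unique()
    if len(lengths) > 1:
        raise ValueError(f"inconsistent UMI lengths in read table: {sorted(lengths)}")

    parts = []
    for (bc, gene), grp in reads.groupby(["barcode", "gene"], sort=False):
        umis, nreads = _collapse_group(grp["umi"].to_numpy(),
                                       grp["reads"].to_numpy())
        parts.append(pd.DataFrame({"barcode": bc, "gene": gene,
                                   "umi": umis, "reads": nreads}))
    out = pd.concat(parts, ignore_index=True)
    return out[READ_TABLE_COLUMNS]


def collapse_umis_bruteforce(reads: pd.DataFrame) -> pd.DataFrame:
    """Reference collapse using exhaustive O(n^2) pairwise hamming distances.

    Same contract and tie-breaks as :func:`collapse_umis`; kept as an
    independent oracle for equivalence testing on small groups.
    """
    _check_read_table(reads)
    if len(reads) == 0:
        return reads.copy()
    parts = []
    for (bc, gene), grp in reads.groupby(["barcode", "gene"], sort=False):
        umis = grp["umi"].to_numpy()
        nreads = grp["reads"].to_numpy()
        out = dict(zip(umis, nreads))
        for u, r in zip(umis, nreads):
            if r != 1:
                continue
            cands = [
                (v, rv) for v, rv in zip(umis, nreads)
                if rv >= 2 and sum(a != b for a, b in zip(u, v)) == 1
            ]
            if cands:
                cands.sort(key=lambda t: (-t[1], t[0]))
                out[cands[0][0]] += 1
                del out[u]
        surv = sorted(out)
        parts.append(pd.DataFrame({"barcode": bc, "gene": gene, "umi": surv,
                                   "reads": [out[u] for u in surv]}))
    return pd.concat(parts, ignore_index=True)[READ_TABLE_COLUMNS]


def reads_to_counts(reads: pd.DataFrame,
                    genes: list[str] | None = None,
                    barcodes: list[str] | None = None,
                    sample_of: dict[str, str] | None = None) -> CountMatrix:
    """Count distinct UMIs per (barcode, gene) into a CountMatrix.

    Gene and barcode universes default to those observed in the table;
    passing explicit lists keeps all-zero rows/columns.
    """
    _check_read_table(reads)
    if genes is None:
        genes = sorted(reads["gene"].unique())
    if barcodes is None:
        barcodes = sorted(reads["barcode"].unique())
    import scipy.sparse as sp

    gidx = {g: i for i, g in enumerate(genes)}
    bidx = {b: i for i, b in enumerate(barcodes)}
    if len(reads):
        tab = (reads.groupby(["barcode", "gene"], sort=False)
               .size().reset_index(name="n"))
        rows = tab["gene"].map(gidx).to_numpy()
        cols = tab["barcode"].map(bidx).to_numpy()
        X = sp.csr_matrix((tab["n"].to_numpy(dtype=np.int64), (rows, cols)),
                          shape=(len(genes), len(barcodes)))
    else:
        X = sp.csr_matrix((len(genes), len(barcodes)), dtype=np.int64)
    labels = np.asarray(
        [sample_of.get(b, "sample1") if sample_of else "sample1" for b in barcodes],
        dtype=object)
    return CountMatrix(genes=list(genes), barcodes=list(barcodes), X=X,
                       sample_of=labels)
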