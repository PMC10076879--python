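"""Over-representation analysis of gene lists against GMT gene-set collections.

The test is the hypergeometric upper tail — identical to the one-sided
Fisher exact test on the 2x2 membership table — evaluated against a
user-chosen universe (by default all genes measured on the platform).
BH correction is applied across the tested sets.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .methylation import bh_adjust


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n).

    k = hits in the query, K = set size in the universe, n = query size,
    N = universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT collection: (name, description, members) per line."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            sets.append((name, desc, members))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for name, desc, members in sets:
            fh.write("\t".join([name, desc, *members]) + "\n")


def enrich(
    query,
    universe,
    collection,
    skip_empty: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    ``collection`` is a list of (name, description, members) tuples as
    returned by :func:`read_gmt`. Query genes outside the universe are
    dropped with a warning. Sets that do not intersect the universe are not
    tested; sets with zero query hits are reported with p = 1 unless
    ``skip_empty``.
    """
    uni = set(universe)
    q = set(query)
    if not q:
        raise ValueError("empty query gene list")
    outside = q - uni
    if outside:
        warnings.warn(f"{len(outside)} query genes outside universe dropped")
        q &= uni
        if not q:
            raise ValueError("no query genes remain inside the universe")
    N, n = len(uni), len(q)
    rows = []
    for name, desc, members in collection:
        in_uni = set(members) & uni
        K = len(in_uni)
        if K == 0:
            continue
        k = len(in_uni & q)
        if k == 0 and skip_empty:
            continue
        rows.append(
            {"term": name, "description": desc, "k": k, "K": K, "n": n, "N": N,
             "p_value": hypergeom_upper_tail(k, K, n, N)}
        )
    res = pd.DataFrame(rows)
    if not res.empty:
        res["fdr"] = bh_adjust(res["p_value"].to_numpy())
        res = res.sort_values(["p_value", "term"]).reset_index(drop=True)
    return res
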