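"""Over-representation analysis and reference-catalogue overlap.

Enrichment of a protein set against GMT-style annotation terms uses the
one-sided upper-tail hypergeometric test (probability of observing at
least the seen overlap between the query and a term, drawing from the
declared universe) with Bonferroni correction across tested terms. The
default universe is the dataset-specific background - all proteins passing
the frequency filter - supplied explicitly by the caller.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd
from scipy import stats

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeom_enrich",
    "catalogue_overlap",
    "plot_enrichment_bars",
]


def read_gmt(path: str | Path) -> dict:
    """Read GMT (term, description, members...) into
    ``{term_id: {"label": ..., "members": set}}``."""
    terms = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        terms[fields[0]] = {"label": fields[1], "members": set(fields[2:])}
    return terms


def write_gmt(terms: Mapping[str, Mapping], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            t = terms[term_id]
            fh.write("\t".join([term_id, t.get("label", term_id),
                                *sorted(t["members"])]) + "\n")
    return path


def hypergeom_enrich(query: Iterable[str], annotation: Mapping[str, Mapping],
                     universe: Iterable[str], alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    For a term with K members in the universe of size N and a query of size
    n overlapping it in k proteins, p_raw = P(X >= k) under the
    hypergeometric null; Bonferroni multiplies by the number of terms
    tested (terms with at least one member in the universe). Results are
    sorted by corrected p. ``percent_of_query`` is 100 k / n, the bar-chart
    quantity.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(
            f"query contains {len(stray)} protein(s) outside the universe: "
            f"{sorted(stray)[:10]}")
    n = len(query)
    N = len(universe)
    rows = []
    tested = []
    for term_id in sorted(annotation):
        members = set(annotation[term_id]["members"]) & universe
        if not members:
            continue
        tested.append(term_id)
        K = len(members)
        k = len(members & query)
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"term_id": term_id,
                     "term_label": annotation[term_id].get("label", term_id),
                     "k": k, "n": n, "K": K, "N": N, "p_raw": min(p_raw, 1.0),
                     "percent_of_query": 100.0 * k / n if n else 0.0})
    m = len(tested)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_bonferroni"] = (df["p_raw"] * m).clip(upper=1.0)
    df["enriched"] = df["p_bonferroni"] < alpha
    return df.sort_values(["p_bonferroni", "p_raw", "term_id"]).reset_index(drop=True)


def catalogue_overlap(query: Iterable[str], reference: Iterable[str]) -> dict:
    """Fraction of the query present in a reference catalogue (e.g. a known
    EV-protein list), with the in/out partition."""
    query = set(query)
    reference = set(reference)
    if not query:
        warnings.warn("empty query: overlap fraction defined as 0", stacklevel=2)
        return {"fraction": 0.0, "in_reference": set(), "not_in_reference": set()}
    inside = query & reference
    return {"fraction": len(inside) / len(query),
            "in_reference": inside,
            "not_in_reference": query - inside}


def plot_enrichment_bars(results: pd.DataFrame, path: str | Path,
                         top: int = 10):
    """Horizontal bar chart of percent-of-query for the top enriched terms."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = results[results["enriched"]].head(top)
    if sub.empty:
        sub = results.head(top)
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(sub), 4) + 1))
    ax.barh(sub["term_label"][::-1], sub["percent_of_query"][::-1])
    ax.set_xlabel("% of query proteins")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
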