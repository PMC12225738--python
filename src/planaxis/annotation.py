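"""Gene-class assignment from domain annotations and class-composition tests.

Domain calls (Pfam-style labels) and signal-peptide flags are inputs — the
pipeline consumes the output of external annotators rather than rerunning
them. A gene belongs to a class when its domain set intersects the class
rule set; the ``secreted`` class is keyed on the signal-peptide flag and
classes may overlap (a receptor can also be secreted-pathway).

:func:`composition_test` asks, per class, whether the class is
over-represented among aborally enriched genes relative to orally enriched
ones, with a one-sided Fisher exact test on the 2x2 membership table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import ContingencyTable, fisher_exact

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CLASS_RULES", "classify_genes", "composition_test"]

#: Class -> qualifying Pfam domain labels. ``secreted`` is special-cased on
#: the signal-peptide flag rather than a domain list.
DEFAULT_CLASS_RULES: dict[str, set[str]] = {
    "GPCR": {"7tm_1", "7tm_2", "7tm_3"},
    "ion_channel": {"Ion_trans", "Lig_chan", "Neur_chan_memb", "Neur_chan_LBD"},
}

SECRETED_CLASS = "secreted"


def classify_genes(
    annotations: pd.DataFrame, rules: dict[str, set[str]] | None = None
) -> dict[str, set[str]]:
    """Map gene_id -> set of class names.

    ``annotations`` columns: ``gene_id``, ``domains`` (semicolon-joined
    labels, may be empty), ``signal_peptide`` (0/1).
    """
    rules = rules if rules is not None else DEFAULT_CLASS_RULES
    if not all(rules.values()):
        raise ValueError("class rule sets must be non-empty")
    out: dict[str, set[str]] = {}
    for row in annotations.itertuples(index=False):
        domains = {d for d in str(row.domains).split(";") if d and d != "nan"}
        classes = {name for name, labels in rules.items() if domains & labels}
        if int(row.signal_peptide):
            classes.add(SECRETED_CLASS)
        out[str(row.gene_id)] = classes
    return out


def composition_test(
    aboral_set: set[str],
    oral_set: set[str],
    classes: dict[str, set[str]],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-class composition of the aboral vs oral enriched sets.

    For each class the 2x2 table is
    ``[[|class ∩ aboral|, |aboral \\ class|], [|class ∩ oral|, |oral \\ class|]]``
    and ``alternative='greater'`` tests aboral over-representation.
    Genes missing from the annotation table contribute empty class sets
    (their number is logged). Returns per class: counts, percentages of
    each set, and the Fisher p-value; empty input sets yield NaN
    percentages and p = 1 with ``degenerate=True``.
    """
    if aboral_set & oral_set:
        raise ValueError("aboral and oral sets must be disjoint")
    missing = sum(1 for g in aboral_set | oral_set if g not in classes)
    if missing:
        logger.info("%d enriched genes missing from the annotation table", missing)
    class_names = sorted({c for cs in classes.values() for c in cs})
    rows = []
    n_ab, n_or = len(aboral_set), len(oral_set)
    degenerate = n_ab == 0 or n_or == 0
    for name in class_names:
        in_ab = sum(1 for g in aboral_set if name in classes.get(g, set()))
        in_or = sum(1 for g in oral_set if name in classes.get(g, set()))
        if degenerate:
            p = 1.0
        else:
            table = ContingencyTable(in_ab, n_ab - in_ab, in_or, n_or - in_or)
            p = fisher_exact(table, alternative=alternative)
        rows.append({
            "class": name,
            "n_aboral": in_ab,
            "n_oral": in_or,
            "aboral_pct": 100.0 * in_ab / n_ab if n_ab else np.nan,
            "oral_pct": 100.0 * in_or / n_or if n_or else np.nan,
            "p": p,
            "degenerate": degenerate,
        })
    return pd.DataFrame(
        rows,
        columns=["class", "n_aboral", "n_oral", "aboral_pct", "oral_pct", "p",
                 "degenerate"],
    )
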