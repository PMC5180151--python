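"""Dereplication and sequence retention rules.

The retention cascade mirrors standard metabarcoding hygiene: amplicon
length check, abundance-ratio error pruning within each PCR replicate, a
reference-identity prescreen that drops sequences without a >= 80% match to
a metazoan barcode (or whose best hit is non-metazoan), a mitochondrial
translation check, and finally a replicate-consistency rule keeping only
sequences seen in at least 3 of the 5 replicate PCRs of a water sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from edna._seqtools import pairwise_identity_matrix

__all__ = [
    "dereplicate", "prune_errors", "identity_prescreen", "translation_filter",
    "replicate_filter", "FilterReport", "run_filters",
]

REASONS = (
    "length", "error_pruned", "identity_lt_80",
    "nonmetazoan_besthit", "untranslatable", "replicate_lt_3",
)


@dataclass
class FilterReport:
    """Per-rule discard bookkeeping; input = retained + sum(discarded)."""

    n_input: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )
    n_retained: int = 0

    def check_conservation(self) -> bool:
        return self.n_input == self.n_retained + sum(self.discarded.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": k, "discarded": v} for k, v in self.discarded.items()]
        rows.append({"rule": "retained", "discarded": self.n_retained})
        rows.append({"rule": "input", "discarded": self.n_input})
        return pd.DataFrame(rows)


def dereplicate(bins: dict[tuple[str, int], list]) -> pd.DataFrame:
    """Exact-string dereplication into a unique-sequence x (sample,
    replicate) count table.

    ``bins`` maps (sample, replicate) to reads (TaggedRead or plain
    strings). Column order follows the bin order; row order is by
    decreasing total count, ties lexicographic.
    """
    from collections import Counter

    per_bin = {
        col: Counter(r if isinstance(r, str) else r.sequence for r in reads)
        for col, reads in bins.items()
    }
    if per_bin:
        table = pd.DataFrame(per_bin).fillna(0).astype(np.int64)
        table.columns = pd.MultiIndex.from_tuples(
            per_bin.keys(), names=["sample", "replicate"]
        )
    else:
        table = pd.DataFrame(
            index=pd.Index([]),
            columns=pd.MultiIndex.from_tuples([], names=["sample", "replicate"]),
            dtype=np.int64,
        )
    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda s: (-totals[s], s))
    return table.loc[order]


def _absorb_column(seqs: list[str], counts: np.ndarray, max_edit: int,
                   abundance_ratio: float) -> np.ndarray:
    """One replicate's absorption pass to fixpoint. Returns updated counts."""
    counts = counts.copy()
    changed = True
    while changed:
        changed = False
        order = sorted(range(len(seqs)), key=lambda i: (-counts[i], seqs[i]))
        # walk children from rarest upwards
        for child in reversed(order):
            c = counts[child]
            if c == 0:
                continue
            best_parent = -1
            for parent in order:
                if counts[parent] < abundance_ratio * c:
                    break  # order is descending; no later parent qualifies
                if parent == child:
                    continue
                hit = edlib.align(seqs[child], seqs[parent], k=max_edit)
                if hit["editDistance"] != -1:
                    best_parent = parent
                    break
            if best_parent >= 0:
                counts[best_parent] += c
                counts[child] = 0
                changed = True
    return counts


def prune_errors(
    table: pd.DataFrame, max_edit: int = 1, abundance_ratio: float = 10.0
) -> pd.DataFrame:
    """Absorb likely PCR/sequencing error variants into abundant parents.

    Within each replicate column, a sequence is absorbed into the most
    abundant parent within ``max_edit`` edits whose count is at least
    ``abundance_ratio`` times its own; absorption transfers the count and
    iterates to a fixpoint. Rows whose total count reaches zero are dropped.
    Total read count is conserved.
    """
    if max_edit < 1:
        raise ValueError("max_edit must be >= 1")
    if abundance_ratio <= 1:
        raise ValueError("abundance_ratio must be > 1")
    seqs = list(table.index)
    out = table.to_numpy().copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.nonzero(col)[0]
        if len(nz) < 2:
            continue
        sub = _absorb_column([seqs[i] for i in nz], col[nz], max_edit, abundance_ratio)
        out[nz, j] = sub
    pruned = pd.DataFrame(out, index=table.index, columns=table.columns)
    return pruned[pruned.sum(axis=1) > 0]


def identity_prescreen(
    seqs: list[str], refdb: list, min_identity: float = 0.80
) -> pd.DataFrame:
    """Best-hit prescreen against a reference barcode collection.

    For each sequence, the best global-alignment identity over all
    references is found. A sequence is discarded when its best hit is
    non-metazoan, or when no metazoan reference reaches ``min_identity``.
    Returns a DataFrame indexed by sequence with columns (keep, reason,
    best_ref, identity).
    """
    if not refdb:
        raise ValueError("reference database is empty")
    idents = pairwise_identity_matrix(seqs, [r.sequence for r in refdb])
    is_meta = np.array([r.is_metazoan for r in refdb])
    rows = []
    for i, seq in enumerate(seqs):
        best = int(np.argmax(idents[i]))
        meta_best = float(idents[i][is_meta].max()) if is_meta.any() else 0.0
        if not refdb[best].is_metazoan:
            rows.append((seq, False, "nonmetazoan_besthit", refdb[best].ref_id,
                         float(idents[i][best])))
        elif meta_best < min_identity:
            rows.append((seq, False, "identity_lt_80", refdb[best].ref_id,
                         float(idents[i][best])))
        else:
            rows.append((seq, True, "", refdb[best].ref_id, float(idents[i][best])))
    return pd.DataFrame(
        rows, columns=["sequence", "keep", "reason", "best_ref", "identity"]
    ).set_index("sequence")


def translation_filter(seq: str) -> bool:
    """Keep a sequence iff some reading frame on the given strand is
    stop-free under the vertebrate (table 2) or invertebrate (table 5)
    mitochondrial code.

    The codes differ at AGA/AGG: stops for vertebrates, serine for
    invertebrates — a sequence clean under either code passes.
    """
    for table in (2, 5):
        for offset in range(3):
            sub = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
            if len(sub) < 3:
                continue
            if "*" not in Seq(sub).translate(table=table):
                return True
    return False


def replicate_filter(
    table: pd.DataFrame, min_replicates: int = 3, n_replicates: int = 5
) -> dict[str, set[str]]:
    """Apply the >= min_replicates-of-n replicate-consistency rule.

    Returns, per sample, the set of unique sequences whose count is
    positive in at least ``min_replicates`` of that sample's replicate
    columns. Samples with a different number of replicate columns than
    ``n_replicates`` trigger a warning and the threshold is applied to the
    replicates that exist.
    """
    if min_replicates > n_replicates:
        raise ValueError("min_replicates must be <= n_replicates")
    retained: dict[str, set[str]] = {}
    for sample in table.columns.get_level_values(0).unique():
        sub = table.xs(sample, axis=1, level=0)
        if sub.shape[1] != n_replicates:
            warnings.warn(
                f"sample {sample}: {sub.shape[1]} replicates (expected "
                f"{n_replicates}); threshold applied to available replicates"
            )
        hits = (sub > 0).sum(axis=1)
        retained[sample] = set(sub.index[hits >= min_replicates])
    return retained


def run_filters(
    table: pd.DataFrame,
    refdb: list,
    expected_length: int = 313,
    length_tolerance: int = 0,
    max_edit: int = 1,
    abundance_ratio: float = 10.0,
    min_identity: float = 0.80,
    min_replicates: int = 3,
    n_replicates: int = 5,
) -> tuple[pd.DataFrame, dict[str, set[str]], FilterReport]:
    """Full retention cascade: length -> error pruning -> identity
    prescreen -> translation -> replicate consistency.

    Returns (filtered unique-sequence table, per-sample retained sets,
    FilterReport over unique sequences).
    """
    report = FilterReport(n_input=table.shape[0])

    lengths = table.index.str.len()
    ok = abs(lengths - expected_length) <= length_tolerance
    report.discarded["length"] = int((~ok).sum())
    table = table[ok]

    pruned = prune_errors(table, max_edit=max_edit, abundance_ratio=abundance_ratio)
    report.discarded["error_pruned"] = table.shape[0] - pruned.shape[0]
    table = pruned

    if table.shape[0]:
        screen = identity_prescreen(list(table.index), refdb, min_identity)
        for reason in ("identity_lt_80", "nonmetazoan_besthit"):
            report.discarded[reason] = int((screen["reason"] == reason).sum())
        table = table[screen["keep"].to_numpy()]

    translatable = np.array([translation_filter(s) for s in table.index], dtype=bool) \
        if table.shape[0] else np.array([], dtype=bool)
    report.discarded["untranslatable"] = int((~translatable).sum())
    table = table[translatable]

    retained = replicate_filter(table, min_replicates, n_replicates)
    union: set[str] = set().union(*retained.values()) if retained else set()
    report.discarded["replicate_lt_3"] = table.shape[0] - len(
        union & set(table.index)
    )
    report.n_retained = len(union & set(table.index))
    table = table[table.index.isin(union)]
    return table, retained, report
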