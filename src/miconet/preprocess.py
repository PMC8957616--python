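"""Compositional preprocessing: taxon filtering, rarefaction, CLR.

The default pipeline mirrors common 16S practice for co-occurrence
inference: taxa are kept only if they pass BOTH a mean relative-abundance
threshold (default 0.01%) and a prevalence threshold (default 37% of
samples with a non-zero count); counts are then centered-log-ratio
transformed with a pseudocount. Rarefaction (without replacement, default
50,000 reads) is available for workflows that require a common depth.
"""

from __future__ import annotations

import logging

import numpy as np

from ._rng import child_rng
from .tables import ClrMatrix, CountTable

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """All rows or columns were removed by a preprocessing step."""


def filter_taxa(
    table: CountTable,
    rel_abund_min: float = 1e-4,
    prevalence_min: float = 0.37,
    abundance_stat: str = "mean",
) -> CountTable:
    """Retain taxa passing both abundance and prevalence thresholds.

    A taxon is retained iff its per-sample relative abundance summary
    (``mean`` or ``max`` across samples) is >= ``rel_abund_min`` AND the
    fraction of samples where it has a non-zero count is >= ``prevalence_min``.
    Sample set and taxon order are preserved. Idempotent.
    """
    if not (0 <= rel_abund_min <= 1 and 0 <= prevalence_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if abundance_stat not in ("mean", "max"):
        raise ValueError("abundance_stat must be 'mean' or 'max'")
    counts = table.counts.to_numpy(dtype=float)
    depths = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(depths > 0, counts / depths, 0.0)
    abund = rel.mean(axis=0) if abundance_stat == "mean" else rel.max(axis=0)
    prevalence = (counts > 0).mean(axis=0)
    pass_abund = abund >= rel_abund_min
    pass_prev = prevalence >= prevalence_min
    keep = pass_abund & pass_prev
    if not keep.any():
        stricter = (
            "prevalence" if pass_prev.sum() < pass_abund.sum() else "relative abundance"
        )
        raise EmptyResultError(
            f"all {table.n_taxa} taxa removed; the {stricter} threshold is the "
            "stricter of the two"
        )
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    logger.info("filter_taxa: kept %d of %d taxa", len(kept), table.n_taxa)
    return table.select_taxa(kept)


def rarefy(table: CountTable, depth: int = 50_000, seed: int = 0) -> CountTable:
    """Subsample every sample to a common depth, without replacement.

    Samples whose total count is below ``depth`` are dropped (and logged);
    a sample at exactly ``depth`` is returned unchanged. Reproducible given
    the seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.depths()
    keep = totals[totals >= depth].index.tolist()
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning(
            "rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped
        )
    if not keep:
        raise EmptyResultError(f"all samples have fewer than {depth} reads")
    sub = table.select_samples(keep)
    rng = child_rng(seed, "rarefy", depth)
    out = sub.counts.to_numpy(dtype=np.int64).copy()
    for i in range(out.shape[0]):
        total = int(out[i].sum())
        if total > depth:
            out[i] = rng.multivariate_hypergeometric(out[i], depth)
    rarefied = sub.counts.copy()
    rarefied.iloc[:, :] = out
    return CountTable(counts=rarefied, metadata=sub.metadata)


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform with additive pseudocount.

    value[s, t] = ln(count[s, t] + pc) - mean_t' ln(count[s, t'] + pc),
    so every row sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logs = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    vals = logs - logs.mean(axis=1, keepdims=True)
    df = table.counts.copy().astype(float)
    df.iloc[:, :] = vals
    return ClrMatrix(
        values=df,
        pseudocount=pseudocount,
        provenance={"n_samples": table.n_samples, "n_taxa": table.n_taxa},
    )
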