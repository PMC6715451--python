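"""Probe re-annotation: alignment-hit filtering and probe-level summarization.

Microarray probe sequences aligned against a transcript catalogue yield a
hit table (probe, probe set, transcript, perfect/imperfect).  Three ordered
filtering rules turn it into a one-to-one probe-set -> transcript map:

1. only perfect-match hits are considered;
2. a probe matching more than one transcript is deleted;
3. a probe set is retained only if all of its surviving probes point at a
   single transcript, and a transcript is retained only if supported by
   more than four surviving probes (i.e. at least five).

Probe-level expression is then summarized to transcript level by the median
across a transcript's surviving probes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .containers import ExpressionDataset

log = logging.getLogger(__name__)

MIN_SUPPORT = 5  # "> 4 probes" read strictly: at least five

HIT_COLUMNS = ["probe_id", "probe_set_id", "transcript_id", "biotype", "perfect_match"]


@dataclass
class ProbeTranscriptMap:
    """Filtered probe-set -> transcript assignment with probe support."""

    mapping: dict[str, str]          # probe_set_id -> transcript_id
    support: dict[str, int]          # transcript_id -> surviving probe count
    probe_to_transcript: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.mapping.values():
            if self.support.get(t, 0) < MIN_SUPPORT:
                raise ValueError(
                    f"transcript {t} mapped with support {self.support.get(t, 0)} < {MIN_SUPPORT}"
                )

    @property
    def transcripts(self) -> set[str]:
        return set(self.mapping.values())


def filter_alignments(hits: pd.DataFrame) -> ProbeTranscriptMap:
    """Apply the three re-annotation rules, in order, to an alignment table.

    The order is forced by well-definedness: only perfect hits are eligible
    (1), ambiguous probes are deleted before anything is counted (2), probe
    sets must be unanimous about their transcript (3), and finally only
    transcripts with >4 surviving probes are retained.
    """
    if hits.empty:
        raise ValueError("alignment hit table is empty")
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table lacks columns {missing}")

    n_dup = hits.duplicated(subset=["probe_id", "transcript_id"]).sum()
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate (probe, transcript) rows")
        hits = hits.drop_duplicates(subset=["probe_id", "transcript_id"])

    # rule 1: perfect matches only
    perfect = hits[hits["perfect_match"].astype(bool)]

    # rule 2: delete probes hitting more than one transcript
    per_probe = perfect.groupby("probe_id")["transcript_id"].nunique()
    ambiguous = set(per_probe.index[per_probe > 1])
    surviving = perfect[~perfect["probe_id"].isin(ambiguous)]

    # rule 3a: a probe set must target exactly one transcript
    per_set = surviving.groupby("probe_set_id")["transcript_id"].nunique()
    unanimous_sets = set(per_set.index[per_set == 1])
    surviving = surviving[surviving["probe_set_id"].isin(unanimous_sets)]

    # rule 3b: a transcript needs more than four surviving probes
    support_all = surviving.groupby("transcript_id")["probe_id"].nunique()
    kept_transcripts = set(support_all.index[support_all >= MIN_SUPPORT])
    final = surviving[surviving["transcript_id"].isin(kept_transcripts)]

    mapping = dict(
        final.groupby("probe_set_id")["transcript_id"].first()
    )
    support = {t: int(support_all[t]) for t in kept_transcripts}
    probe_map = dict(zip(final["probe_id"], final["transcript_id"]))

    if not mapping:
        warnings.warn("no probe set survived the re-annotation filters")
    log.info(
        "re-annotation: %d hits -> %d probe sets over %d transcripts",
        len(hits), len(mapping), len(kept_transcripts),
    )
    return ProbeTranscriptMap(mapping=mapping, support=support,
                              probe_to_transcript=probe_map)


def summarize_expression(
    probe_matrix: pd.DataFrame,
    pmap: ProbeTranscriptMap,
    labels: pd.Series | None = None,
    contrast: tuple[str, str] | None = None,
    biotype: pd.Series | None = None,
) -> pd.DataFrame | ExpressionDataset:
    """Collapse a probe x sample matrix to transcript level (median of probes).

    Probes absent from the filtered map are dropped.  If ``labels`` (and
    ``contrast``, ``biotype``) are given, an :class:`ExpressionDataset` is
    returned; otherwise the plain transcript x sample DataFrame.
    """
    keep = [p for p in probe_matrix.index if p in pmap.probe_to_transcript]
    if not keep:
        raise ValueError("no probe row of the matrix appears in the filtered map")
    sub = probe_matrix.loc[keep]
    transcripts = pd.Series(
        [pmap.probe_to_transcript[p] for p in keep], index=keep
    )
    out = sub.groupby(transcripts).median()
    out = out.loc[sorted(out.index)]
    if labels is None:
        return out
    assert contrast is not None and biotype is not None
    return ExpressionDataset(
        matrix=out, labels=labels, contrast=contrast, biotype=biotype.loc[out.index]
    )


def blast_outfmt6_to_hits(
    blast: pd.DataFrame,
    probe_sets: pd.Series,
    biotypes: pd.Series,
    probe_length: int = 25,
) -> pd.DataFrame:
    """Adapter from a BLAST outfmt-6-like table to the hit-table schema.

    A hit is perfect when percent identity is 100 and the alignment spans the
    full probe length.  ``probe_sets`` maps probe id -> probe set id and
    ``biotypes`` maps transcript id -> biotype.
    """
    required = ["qseqid", "sseqid", "pident", "length"]
    missing = [c for c in required if c not in blast.columns]
    if missing:
        raise ValueError(f"BLAST table lacks columns {missing}")
    return pd.DataFrame({
        "probe_id": blast["qseqid"],
        "probe_set_id": blast["qseqid"].map(probe_sets),
        "transcript_id": blast["sseqid"],
        "biotype": blast["sseqid"].map(biotypes),
        "perfect_match": (blast["pident"] == 100.0) & (blast["length"] == probe_length),
    })
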