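"""Cross-crew transcript catalog analysis.

A de novo assembly run per sample yields a catalog of transcripts, each
carrying a one-letter class code describing its relation to the reference
annotation. This module answers two questions about such catalogs across a
crew of subjects sampled at several timepoints:

* which transcripts are found *consistently* — present in every subject's
  retained sample at a timepoint (strict consensus); and
* which of those are *unique* to one timepoint within a window — absent from
  every retained sample at every other timepoint of the window.

Presence is held to the strict all-subject consensus while absence is held to
the strict no-sample standard; the asymmetry maximizes specificity of the
"unique transcript" call. Samples failing read-length QC are removed before
either check, and a whole timepoint can optionally be dropped when any of its
samples fails (the stricter behavior appropriate when one bad sample makes a
timepoint's consensus unrepresentative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import CLASS_CODES, FormatError, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptCatalog",
    "UniqueTranscriptReport",
    "flag_low_quality",
    "consensus_presence",
    "unique_transcripts",
    "class_code_tally",
]


@dataclass
class TranscriptCatalog:
    """Per-sample transcript presence with class codes.

    ``info`` is indexed by transcript id with columns ``locus_id``,
    ``ref_match`` (None for novel transcripts) and ``class_code``;
    ``presence`` is a boolean transcript x sample frame; ``sample_map``
    maps each sample id to its (subject, timepoint) pair.
    """

    info: pd.DataFrame
    presence: pd.DataFrame
    sample_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.info.index.equals(self.presence.index):
            raise FormatError("info and presence transcript ids differ")
        bad = set(self.info["class_code"]) - CLASS_CODES
        if bad:
            raise FormatError(f"unknown class code(s): {sorted(bad)}")
        unknown = set(self.sample_map) - set(self.presence.columns)
        if unknown:
            raise FormatError(f"sample_map names unknown samples: {sorted(unknown)}")

    def with_sample_meta(self, metas: list[SampleMeta]) -> "TranscriptCatalog":
        """Attach (subject, timepoint) mapping from a sample sheet."""
        by_id = {m.sample_id: (m.subject_id, m.timepoint_label) for m in metas}
        missing = [s for s in self.presence.columns if s not in by_id]
        if missing:
            raise FormatError(f"sample sheet lacks catalog samples: {missing}")
        return TranscriptCatalog(
            info=self.info,
            presence=self.presence,
            sample_map={s: by_id[s] for s in self.presence.columns},
        )

    def timepoints(self) -> list[str]:
        return sorted({tp for _, tp in self.sample_map.values()})

    def samples_at(self, timepoint: str) -> list[str]:
        return [
            s for s, (_, tp) in self.sample_map.items() if tp == timepoint
        ]

    def drop_samples(self, sample_ids: list[str]) -> "TranscriptCatalog":
        keep = [s for s in self.presence.columns if s not in set(sample_ids)]
        return TranscriptCatalog(
            info=self.info,
            presence=self.presence.loc[:, keep],
            sample_map={s: v for s, v in self.sample_map.items() if s in set(keep)},
        )


@dataclass
class UniqueTranscriptReport:
    """Timepoint-unique transcripts within one analysis window."""

    window: list[str]
    unique: dict[str, set[str]]  # timepoint -> transcript ids
    class_codes: dict[str, str]  # transcript id -> class code

    def counts(self) -> dict[str, int]:
        return {tp: len(self.unique[tp]) for tp in self.window}


def flag_low_quality(
    sample_meta: list[SampleMeta], min_avg_read_len: float = 400.0
) -> list[str]:
    """Sample ids whose average read length falls below the threshold.

    Degraded runs with short average read length have depressed
    transcript-level sensitivity and would contaminate both the consensus and
    the absence checks; they are excluded from catalog analyses. A missing QC
    field is an error — silent inclusion of an unmeasured sample defeats the
    point of the filter.
    """
    excluded = []
    for m in sample_meta:
        if m.avg_read_length_bp is None:
            raise FormatError(
                f"sample {m.sample_id!r} lacks avg_read_length_bp; "
                "QC field required for catalog analyses"
            )
        if m.avg_read_length_bp < min_avg_read_len:
            logger.info(
                "excluding sample %s (avg read length %.0f bp < %.0f bp)",
                m.sample_id, m.avg_read_length_bp, min_avg_read_len,
            )
            excluded.append(m.sample_id)
    return excluded


def consensus_presence(catalog: TranscriptCatalog, timepoint: str) -> set[str]:
    """Transcripts present in *every* retained subject's sample at a timepoint."""
    samples = catalog.samples_at(timepoint)
    if not samples:
        raise FormatError(f"no retained samples at timepoint {timepoint!r}")
    present_all = catalog.presence[samples].all(axis=1)
    return set(catalog.presence.index[present_all])


def unique_transcripts(
    catalog: TranscriptCatalog,
    window: list[str],
    min_subjects: int | None = None,
) -> UniqueTranscriptReport:
    """Transcripts unique to one timepoint within a window.

    A transcript is unique to timepoint T iff it passes the consensus at T
    (all retained subjects; or at least ``min_subjects`` of them if given)
    and is absent from every retained sample at every other timepoint of the
    window. Uniqueness sets within a window are therefore pairwise disjoint,
    and enlarging the window can only shrink them.
    """
    if len(window) < 2:
        raise FormatError("uniqueness needs a window of >=2 timepoints")
    known = set(catalog.timepoints())
    missing = [tp for tp in window if tp not in known]
    if missing:
        raise FormatError(f"window timepoints absent from catalog: {missing}")
    unique: dict[str, set[str]] = {}
    for tp in window:
        samples = catalog.samples_at(tp)
        if min_subjects is None:
            candidates = consensus_presence(catalog, tp)
        else:
            n_present = catalog.presence[samples].sum(axis=1)
            candidates = set(catalog.presence.index[n_present >= min_subjects])
        other_samples = [
            s for other in window if other != tp for s in catalog.samples_at(other)
        ]
        if other_samples:
            seen_elsewhere = catalog.presence[other_samples].any(axis=1)
            absent = set(catalog.presence.index[~seen_elsewhere])
            candidates &= absent
        unique[tp] = candidates
    codes = {
        t: catalog.info.loc[t, "class_code"]
        for tps in unique.values()
        for t in tps
    }
    return UniqueTranscriptReport(window=list(window), unique=unique, class_codes=codes)


def class_code_tally(
    transcript_set: set[str], catalog: TranscriptCatalog
) -> dict[str, int]:
    """Count class codes in a transcript set, zero-filled over the alphabet."""
    missing = transcript_set - set(catalog.info.index)
    if missing:
        raise FormatError(f"transcripts not in catalog: {sorted(missing)[:5]}")
    tally = {code: 0 for code in sorted(CLASS_CODES)}
    for t in transcript_set:
        tally[catalog.info.loc[t, "class_code"]] += 1
    return tally
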