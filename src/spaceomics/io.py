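"""Readers and writers for every external table the pipeline touches.

All tabular formats are TSV (UTF-8, header row). Readers validate strictly
and raise :class:`FormatError` naming the offending line or cell rather than
silently coercing; writers are exact round-trip partners of the readers.

The mission timepoint vocabulary is fixed to the seven blood draws of the
study design (three pre-flight, the day after return, three recovery draws),
but an alternative ``label -> signed days`` map may be supplied for reuse on
other mission designs: the downstream trend machinery only needs signed days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINT_DAYS",
    "PREFLIGHT_LABELS",
    "RETURN_LABEL",
    "RECOVERY_LABELS",
    "FormatError",
    "SampleMeta",
    "CountMatrix",
    "GeneSetDB",
    "phase_of_day",
    "read_sample_sheet",
    "read_gmt",
    "read_counts",
    "write_counts",
    "read_tracking",
    "write_tracking",
]

#: Fixed bijection between mission timepoint labels and signed days
#: (negative = days before launch, positive = days after return to Earth).
TIMEPOINT_DAYS: dict[str, int] = {
    "L-92": -92,
    "L-44": -44,
    "L-3": -3,
    "R+1": 1,
    "R+45": 45,
    "R+82": 82,
    "R+194": 194,
}

PREFLIGHT_LABELS = ("L-92", "L-44", "L-3")
RETURN_LABEL = "R+1"
RECOVERY_LABELS = ("R+45", "R+82", "R+194")


class FormatError(ValueError):
    """Malformed external input (bad cell, unknown label, ragged row...)."""


def phase_of_day(time_days: int) -> str:
    """Mission phase of a signed day: ``preflight`` (<0), ``return`` (+1),
    ``recovery`` (>1). Day 0 and other non-mission days are rejected."""
    if time_days < 0:
        return "preflight"
    if time_days == 1:
        return "return"
    if time_days > 1:
        return "recovery"
    raise FormatError(f"day {time_days} is not a valid mission day")


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: a (subject, timepoint) blood draw."""

    sample_id: str
    subject_id: str
    timepoint_label: str
    time_days: int
    phase: str
    avg_read_length_bp: float | None = None

    @classmethod
    def from_label(
        cls,
        sample_id: str,
        subject_id: str,
        timepoint_label: str,
        avg_read_length_bp: float | None = None,
        label_days: Mapping[str, int] = TIMEPOINT_DAYS,
    ) -> "SampleMeta":
        if timepoint_label not in label_days:
            raise FormatError(
                f"unknown timepoint label {timepoint_label!r} for sample "
                f"{sample_id!r} (known: {', '.join(label_days)})"
            )
        days = int(label_days[timepoint_label])
        return cls(
            sample_id=sample_id,
            subject_id=subject_id,
            timepoint_label=timepoint_label,
            time_days=days,
            phase=phase_of_day(days),
            avg_read_length_bp=avg_read_length_bp,
        )


def read_sample_sheet(
    path: str | Path,
    label_days: Mapping[str, int] = TIMEPOINT_DAYS,
) -> list[SampleMeta]:
    """Read a sample sheet TSV into validated :class:`SampleMeta` rows.

    Required columns: ``sample_id``, ``subject_id``, ``timepoint_label``.
    Optional: ``avg_read_length_bp``. ``time_days`` and ``phase`` are filled
    from the label map; duplicated (subject, timepoint) pairs and unknown
    labels are hard errors naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "subject_id", "timepoint_label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    metas: list[SampleMeta] = []
    seen_pairs: set[tuple[str, str]] = set()
    seen_ids: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        try:
            arl = row.get("avg_read_length_bp")
            arl_val = None if arl is None or pd.isna(arl) else float(arl)
            meta = SampleMeta.from_label(
                str(row["sample_id"]),
                str(row["subject_id"]),
                str(row["timepoint_label"]),
                avg_read_length_bp=arl_val,
                label_days=label_days,
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{line}: {exc}") from None
        key = (meta.subject_id, meta.timepoint_label)
        if key in seen_pairs:
            raise FormatError(
                f"{path}:{line}: duplicate (subject, timepoint) pair {key}"
            )
        if meta.sample_id in seen_ids:
            raise FormatError(
                f"{path}:{line}: duplicate sample_id {meta.sample_id!r}"
            )
        seen_pairs.add(key)
        seen_ids.add(meta.sample_id)
        metas.append(meta)
    return metas


def write_sample_sheet(metas: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "timepoint_label": m.timepoint_label,
            "time_days": m.time_days,
            "phase": m.phase,
            "avg_read_length_bp": m.avg_read_length_bp,
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class CountMatrix:
    """A gene x sample expression count matrix.

    Values are non-negative reals — fractional counts are legal because
    multi-mapping-aware quantifiers distribute reads fractionally across
    homologous genes. Gene and sample identifiers are opaque strings and must
    be unique; versioned Ensembl ids are never reconciled implicitly (use
    :meth:`strip_gene_versions` explicitly if two tables disagree on
    versioning).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            gi, si = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"missing value at gene {data.index[gi]!r}, "
                f"sample {data.columns[si]!r}"
            )
        if (values < 0).any():
            gi, si = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count {values[gi, si]} at gene {data.index[gi]!r}, "
                f"sample {data.columns[si]!r}"
            )
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)

    def invalid_samples(self) -> list[str]:
        """Samples whose column sum is not positive (flagged, not dropped)."""
        sizes = self.library_sizes()
        return list(sizes.index[sizes <= 0])

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(sample_ids)])

    def strip_gene_versions(self) -> "CountMatrix":
        """Drop a trailing ``.N`` version suffix from every gene id.

        Explicit opt-in only; raises if stripping creates collisions."""
        stripped = self.data.copy()
        stripped.index = [g.rsplit(".", 1)[0] if "." in g else g for g in stripped.index]
        return CountMatrix(stripped)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            gene = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise FormatError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
    try:
        return CountMatrix(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV; ``read_counts`` round-trips exactly.

    Floats are serialized with ``repr`` (pandas default), which is lossless
    for IEEE doubles.
    """
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GeneSetDB:
    """Named gene sets (pathways), e.g. a curated MSigDb collection."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetDB:
    """Read a GMT gene-set file (name, description, gene ids...).

    Duplicate genes within one line are collapsed with a warning; a repeated
    set name or a line with fewer than three fields is a hard error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set {name!r}")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} lists duplicate gene ids; "
                    "de-duplicated",
                    stacklevel=2,
                )
            if not unique:
                raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetDB(sets=sets, descriptions=descriptions)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in db.items():
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


#: The one-letter transcript classification alphabet used by reference
#: comparison of assembled transcripts (exact match, contained, novel
#: junction, fully novel / intergenic, ...).
CLASS_CODES = frozenset("=ckmnjeosxiypru")


def read_tracking(path: str | Path):
    """Read a transcript-tracking table into a :class:`~spaceomics.denovo.TranscriptCatalog`.

    Dialect: tab-separated columns — transfrag id, locus id, reference match
    (``-`` if none), class code, then one column per sample where ``-`` means
    the transcript was not assembled in that sample. Rows absent from every
    sample are dropped with a warning; an unknown class code or a ragged row
    is a hard error.

    Sample ids are taken from a header line starting with ``#`` if present,
    else named ``q1..qN`` positionally.
    """
    from .denovo import TranscriptCatalog  # deferred: avoid import cycle

    rows = []
    sample_ids: list[str] | None = None
    width: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().split("\t")
                if len(header) > 4:
                    sample_ids = header[4:]
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
                if width < 5:
                    raise FormatError(
                        f"{path}:{lineno}: need >=5 columns (id, locus, ref, "
                        f"class code, samples...), got {width}"
                    )
            elif len(fields) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {width})"
                )
            tid, locus, ref, code = fields[:4]
            if code not in CLASS_CODES:
                raise FormatError(
                    f"{path}:{lineno}: unknown class code {code!r}"
                )
            present = [f != "-" for f in fields[4:]]
            if not any(present):
                warnings.warn(
                    f"{path}:{lineno}: transcript {tid!r} absent from every "
                    "sample; dropped",
                    stacklevel=2,
                )
                continue
            rows.append((tid, locus, None if ref == "-" else ref, code, present))
    n_samples = (width or 5) - 4
    if sample_ids is None:
        sample_ids = [f"q{i + 1}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: header names {len(sample_ids)} samples but rows have "
            f"{n_samples} sample columns"
        )
    info = pd.DataFrame(
        [(t, l, r, c) for t, l, r, c, _ in rows],
        columns=["transcript_id", "locus_id", "ref_match", "class_code"],
    ).set_index("transcript_id")
    if info.index.has_duplicates:
        dup = info.index[info.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate transcript id {dup!r}")
    presence = pd.DataFrame(
        [p for *_, p in rows], index=info.index, columns=sample_ids, dtype=bool
    )
    return TranscriptCatalog(info=info, presence=presence, sample_map={})


def write_tracking(catalog, path: str | Path) -> None:
    """Write a catalog in the tracking dialect read by :func:`read_tracking`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#transcript_id\tlocus_id\tref_match\tclass_code\t"
            + "\t".join(catalog.presence.columns)
            + "\n"
        )
        for tid, row in catalog.info.iterrows():
            flags = [
                f"{tid}|present" if p else "-"
                for p in catalog.presence.loc[tid]
            ]
            ref = row["ref_match"] if row["ref_match"] is not None else "-"
            fh.write(
                "\t".join([tid, row["locus_id"], ref, row["class_code"], *flags])
                + "\n"
            )
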