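"""Genome quality screening and gene-family presence calling.

Turns CheckM-style quality metrics and HMMER ``domtblout`` search results
into a curated genome set and a binary genomes x gene-families presence
matrix with core/accessory prevalence labels.

Hit filtering follows the KOfam convention: a family with a curated
bitscore threshold is judged on bitscore alone; a family without one
falls back to an e-value cutoff combined with a minimum query (profile)
coverage. Coverage is the fraction of the HMM profile spanned by the
union of the reported domain alignments, because the profile is the
query in ``hmmsearch``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "CheckmRecord",
    "GeneHit",
    "ProfileMeta",
    "InvalidRecordError",
    "DomtblParseError",
    "read_checkm_table",
    "filter_genomes",
    "parse_domtbl",
    "read_profile_meta",
    "exclude_small_families",
    "apply_thresholds",
    "best_hit_per_family",
    "build_presence_matrix",
    "classify_gene_prevalence",
    "select_marker_genomes",
]


class InvalidRecordError(ValueError):
    """A quality record violates its invariants (names the genome)."""


class DomtblParseError(ValueError):
    """A domtblout line could not be parsed (carries the line number)."""


@dataclass(frozen=True)
class CheckmRecord:
    """One genome's CheckM quality estimate."""

    genome_id: str
    completeness: float  # percent, [0, 100]
    contamination: float  # percent, >= 0

    def validate(self) -> None:
        if not (0.0 <= self.completeness <= 100.0):
            raise InvalidRecordError(
                f"genome {self.genome_id!r}: completeness {self.completeness} "
                "outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise InvalidRecordError(
                f"genome {self.genome_id!r}: negative contamination "
                f"{self.contamination}"
            )


@dataclass(frozen=True)
class GeneHit:
    """One profile-vs-ORF match (one or more merged domain alignments)."""

    genome_id: str
    family_id: str
    orf_id: str
    bitscore: float
    evalue: float
    profile_span: tuple[int, int]  # half-open [from-1, to) in profile coords
    profile_length: int

    @property
    def coverage(self) -> float:
        lo, hi = self.profile_span
        return (hi - lo) / self.profile_length


@dataclass(frozen=True)
class ProfileMeta:
    """Per-family profile metadata: KEGG threshold and database support."""

    family_id: str
    kegg_bitscore_threshold: float | None
    n_known_sequences: int


# ---------------------------------------------------------------------------
# CheckM quality filter
# ---------------------------------------------------------------------------

def read_checkm_table(path) -> list[CheckmRecord]:
    """Read a tab-separated CheckM quality table.

    Expects columns ``Bin Id``, ``Completeness``, ``Contamination``
    (case-insensitive match, extra columns ignored).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().replace("_", " "): c for c in df.columns}
    try:
        bin_col = cols["bin id"]
        comp_col = cols["completeness"]
        cont_col = cols["contamination"]
    except KeyError as exc:
        raise InvalidRecordError(
            f"CheckM table {path} missing required column: {exc}"
        ) from exc
    return [
        CheckmRecord(str(r[bin_col]), float(r[comp_col]), float(r[cont_col]))
        for _, r in df.iterrows()
    ]


def filter_genomes(
    records: Sequence[CheckmRecord],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> list[str]:
    """Return genome ids passing both quality bounds, in input order.

    A genome is removed when either bound is violated: completeness below
    ``min_completeness`` or contamination above ``max_contamination``.
    Idempotent: filtering an already-filtered set changes nothing.
    """
    if not records:
        raise ValueError("no quality records supplied")
    if not (0.0 <= min_completeness <= 100.0):
        raise ValueError(f"min_completeness {min_completeness} outside [0, 100]")
    if max_contamination < 0.0:
        raise ValueError(f"max_contamination {max_contamination} negative")
    kept: list[str] = []
    for rec in records:
        rec.validate()
        if rec.completeness >= min_completeness and rec.contamination <= max_contamination:
            kept.append(rec.genome_id)
    return kept


# ---------------------------------------------------------------------------
# domtblout parsing
# ---------------------------------------------------------------------------

# HMMER 3.x --domtblout: 22 whitespace-delimited columns + free-text description.
_DOMTBL_MIN_FIELDS = 22


def parse_domtbl(stream, genome_id: str | None = None) -> list[GeneHit]:
    """Parse HMMER 3.x per-domain tabular output into gene hits.

    ``stream`` is a file path or an iterable of lines. Multiple domains of
    the same ORF against the same profile are merged into one hit: the
    profile span is the union of domain spans (total covered positions)
    and score/e-value are the full-sequence values of the best line.

    The target (ORF) name is column 1, the query profile name column 4
    (falling back to column 5's accession if the name is ``-``). The
    genome id defaults to a ``genome|orf`` prefix of the target name when
    not given.
    """
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        with open(stream) as fh:
            return parse_domtbl(fh, genome_id=genome_id)

    # (genome, family, orf) -> accumulated evidence
    acc: dict[tuple[str, str, str], dict] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _DOMTBL_MIN_FIELDS:
            raise DomtblParseError(
                f"line {lineno}: expected >= {_DOMTBL_MIN_FIELDS} columns, "
                f"got {len(fields)}"
            )
        try:
            orf = fields[0]
            family = fields[3] if fields[3] != "-" else fields[4]
            qlen = int(fields[5])
            full_evalue = float(fields[6])
            full_score = float(fields[7])
            hmm_from = int(fields[15])
            hmm_to = int(fields[16])
        except ValueError as exc:
            raise DomtblParseError(f"line {lineno}: {exc}") from exc
        gid = genome_id if genome_id is not None else orf.split("|")[0]
        key = (gid, family, orf)
        ent = acc.setdefault(
            key,
            {"score": full_score, "evalue": full_evalue, "qlen": qlen, "spans": []},
        )
        ent["spans"].append((hmm_from - 1, hmm_to))  # 1-based inclusive -> half-open
        if full_score > ent["score"]:
            ent["score"], ent["evalue"] = full_score, full_evalue

    hits = []
    for (gid, family, orf), ent in acc.items():
        covered = _union_length(ent["spans"])
        # represent the union as a synthetic span of equal length
        hits.append(
            GeneHit(
                genome_id=gid,
                family_id=family,
                orf_id=orf,
                bitscore=ent["score"],
                evalue=ent["evalue"],
                profile_span=(0, covered),
                profile_length=ent["qlen"],
            )
        )
    return hits


def _union_length(spans: Iterable[tuple[int, int]]) -> int:
    total, last_end = 0, -1
    for lo, hi in sorted(spans):
        lo = max(lo, last_end)
        if hi > lo:
            total += hi - lo
            last_end = hi
        last_end = max(last_end, hi)
    return total


# ---------------------------------------------------------------------------
# Profile metadata and hit thresholds
# ---------------------------------------------------------------------------

def read_profile_meta(path) -> dict[str, ProfileMeta]:
    """Read a TSV of (family_id, threshold-or-NA, n_known_sequences)."""
    df = pd.read_csv(
        path, sep="\t", names=["family_id", "threshold", "n_known_sequences"],
        header=None, comment="#",
    )
    # tolerate a header row
    if df.iloc[0]["family_id"] == "family_id":
        df = df.iloc[1:]
    out = {}
    for _, r in df.iterrows():
        thr_raw = r["threshold"]
        thr = None
        if not (pd.isna(thr_raw) or str(thr_raw).upper() in {"NA", "NONE", "-"}):
            thr = float(thr_raw)
            if not math.isfinite(thr):
                raise ValueError(f"non-finite threshold for family {r['family_id']}")
        out[str(r["family_id"])] = ProfileMeta(
            str(r["family_id"]), thr, int(r["n_known_sequences"])
        )
    return out


def exclude_small_families(
    profiles: dict[str, ProfileMeta], min_seqs: int = 200
) -> dict[str, ProfileMeta]:
    """Drop families with fewer than ``min_seqs`` known sequences (strict <)."""
    if min_seqs < 0:
        raise ValueError("min_seqs must be >= 0")
    return {k: p for k, p in profiles.items() if p.n_known_sequences >= min_seqs}


def apply_thresholds(
    hits: Sequence[GeneHit],
    profiles: dict[str, ProfileMeta],
    fallback_evalue: float = 1e-20,
    min_query_cover: float = 0.75,
) -> list[GeneHit]:
    """Keep hits passing the family's reporting threshold.

    A family with a curated bitscore threshold keeps a hit iff
    ``bitscore >= threshold`` (coverage not considered). Without one, a
    hit must satisfy both ``evalue <= fallback_evalue`` and
    ``coverage >= min_query_cover``.
    """
    kept = []
    for h in hits:
        meta = profiles.get(h.family_id)
        if meta is None:
            raise KeyError(f"hit references unknown family {h.family_id!r}")
        if meta.kegg_bitscore_threshold is not None:
            if h.bitscore >= meta.kegg_bitscore_threshold:
                kept.append(h)
        elif h.evalue <= fallback_evalue and h.coverage >= min_query_cover:
            kept.append(h)
    return kept


def best_hit_per_family(hits: Sequence[GeneHit]) -> list[GeneHit]:
    """Reduce to one hit per (genome, family): highest bitscore.

    Ties break by lower e-value, then lexicographically smallest ORF id,
    so the result is deterministic regardless of input order.
    """
    best: dict[tuple[str, str], GeneHit] = {}
    for h in hits:
        key = (h.genome_id, h.family_id)
        cur = best.get(key)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[key] = h
    return [best[k] for k in sorted(best)]


def _hit_rank(h: GeneHit) -> tuple[float, float, str]:
    return (-h.bitscore, h.evalue, h.orf_id)


# ---------------------------------------------------------------------------
# Presence matrix and prevalence labels
# ---------------------------------------------------------------------------

def build_presence_matrix(
    hits: Sequence[GeneHit],
    genomes: Sequence[str],
    families: Sequence[str],
) -> pd.DataFrame:
    """Binary genomes x families matrix: 1 iff >= 1 surviving hit.

    Hits for genomes or families outside the given index sets are
    ignored; genomes with no hits get all-zero rows. Output is invariant
    to hit order and to duplicate hits.
    """
    if len(genomes) == 0 or len(families) == 0:
        raise ValueError("genomes and families must be non-empty")
    if len(set(genomes)) != len(genomes) or len(set(families)) != len(families):
        raise ValueError("genome and family labels must be unique")
    mat = pd.DataFrame(
        np.zeros((len(genomes), len(families)), dtype=np.int8),
        index=list(genomes),
        columns=list(families),
    )
    gset, fset = set(genomes), set(families)
    for h in hits:
        if h.genome_id in gset and h.family_id in fset:
            mat.at[h.genome_id, h.family_id] = 1
    return mat


def classify_gene_prevalence(
    matrix: pd.DataFrame, core_min_fraction: float = 0.9
) -> pd.DataFrame:
    """Label each family core / accessory / absent by column prevalence.

    core iff prevalence >= ``core_min_fraction`` (inclusive), accessory
    iff strictly between 0 and the threshold, absent iff 0. Returns a
    frame indexed by family with ``prevalence`` and ``label`` columns.
    """
    prev = matrix.mean(axis=0).astype(float)
    label = pd.Series(
        np.where(prev >= core_min_fraction, "core",
                 np.where(prev > 0, "accessory", "absent")),
        index=prev.index,
    )
    return pd.DataFrame({"prevalence": prev, "label": label})


def select_marker_genomes(
    hits: Sequence[GeneHit], marker_family: str
) -> dict[str, str]:
    """Genomes with >= 1 surviving hit for the marker gene family.

    Returns genome id -> best-hit ORF id (highest bitscore, standard
    tie-breaks). The study used the ppk1 family (K00937) as its
    phylogenetic marker; genomes with no marker hit are discarded.
    """
    marker_hits = [h for h in hits if h.family_id == marker_family]
    return {h.genome_id: h.orf_id for h in best_hit_per_family(marker_hits)}
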