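"""Central-channel eligibility of nuclear envelope transmembrane proteins.

A NET can engage the NPC's central channel only if (i) it carries a strong
nuclear localization signal (NLS) in an extraluminal domain so a transport
receptor can bind it, and (ii) a sufficiently long intrinsically disordered
(ID) stretch lets that domain reach across the ~20 nm structural scaffold
separating the membrane from the central channel, and (iii) the two are
arranged NLS -> ID run -> transmembrane anchor within one extraluminal
domain.  At an extended backbone length of 0.45 nm per residue, spanning
20 nm takes about 65 disordered residues.

NLS scores, disorder calls and secondary-structure calls are consumed as
precomputed per-residue tracks (from SeqNLS, MetaDisorder, Chou-Fasman and
Garnier-Robson respectively); this module only applies the eligibility rule
and summarizes cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NETRecord",
    "ClassifierConfig",
    "ClassificationResult",
    "parse_net_annotations",
    "write_net_annotations",
    "reach_nm",
    "classify_net",
    "cohort_summary",
]

CATEGORIES = ("Both", "NLS-only", "ID-only", "Neither")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the eligibility rule.

    nls_threshold: minimum NLS prediction score counted as strong (0.86,
    the high-confidence cutoff recommended for the predictor).
    min_id_length: minimum disordered run, residues (65, the number needed
    to span the scaffold at 0.45 nm/residue).
    residue_extension: extended backbone length per residue, nm.
    scaffold_span: radial thickness of the NPC scaffold to cross, nm.
    max_gap: longest interruption (residues) tolerated inside an ID run.
    structure_veto: "any" vetoes a residue when either secondary-structure
    predictor calls structure (strictest reading); "all" requires both.
    """

    nls_threshold: float = 0.86
    min_id_length: int = 65
    residue_extension: float = 0.45
    scaffold_span: float = 20.0
    max_gap: int = 0
    structure_veto: str = "any"

    def __post_init__(self) -> None:
        if not 0.0 < self.nls_threshold <= 1.0:
            raise ValueError("nls_threshold must lie in (0, 1]")
        if self.min_id_length < 1:
            raise ValueError("min_id_length must be at least 1")
        if self.residue_extension <= 0:
            raise ValueError("residue_extension must be positive")
        if self.structure_veto not in ("any", "all"):
            raise ValueError("structure_veto must be 'any' or 'all'")


Interval = tuple[int, int]  # 1-based inclusive residue interval


@dataclass(frozen=True)
class NETRecord:
    """One NET with topology and per-residue prediction tracks.

    Intervals are 1-based inclusive.  ``disorder``, ``cf_structured`` and
    ``gr_structured`` are boolean arrays of length ``length`` (disorder
    from the meta-predictor; structure calls from the two secondary-
    structure algorithms).
    """

    id: str
    localization_class: str  # "INM" or "ONM"
    length: int
    tm_segments: tuple[Interval, ...]
    extraluminal_domains: tuple[Interval, ...]
    nls_hits: tuple[tuple[Interval, float], ...]
    disorder: np.ndarray = field(repr=False)
    cf_structured: np.ndarray = field(repr=False)
    gr_structured: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if self.localization_class not in ("INM", "ONM"):
            raise ValueError("localization_class must be INM or ONM")
        for iv in self.tm_segments + self.extraluminal_domains:
            _check_interval(iv, self.length)
        for iv, score in self.nls_hits:
            _check_interval(iv, self.length)
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"NLS score {score} outside [0, 1]")
        for a, b in _pairs(self.tm_segments):
            if _overlap(a, b):
                raise ValueError("TM segments overlap")
        for a, b in _pairs(self.extraluminal_domains):
            if _overlap(a, b):
                raise ValueError("extraluminal domains overlap")
        for track in (self.disorder, self.cf_structured, self.gr_structured):
            if len(track) != self.length:
                raise ValueError("per-residue track length mismatch")


def _check_interval(iv: Interval, length: int) -> None:
    lo, hi = iv
    if not (1 <= lo <= hi <= length):
        raise ValueError(f"interval {iv} outside [1, {length}]")


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def reach_nm(n_residues: int, config: ClassifierConfig | None = None) -> float:
    """Extended reach of a disordered stretch: residues x nm-per-residue."""
    if n_residues < 0:
        raise ValueError("n_residues must be non-negative")
    config = config or ClassifierConfig()
    return n_residues * config.residue_extension


@dataclass(frozen=True)
class ClassificationResult:
    id: str
    localization_class: str
    category: str  # one of CATEGORIES
    qualifying_nls: tuple[tuple[Interval, float], ...]
    qualifying_id_runs: tuple[Interval, ...]
    arrangement_ok: bool
    reach_nm: float  # extended reach of the longest qualifying ID run


def _id_runs(record: NETRecord, config: ClassifierConfig) -> list[Interval]:
    """Maximal qualifying-disorder runs, 1-based inclusive intervals."""
    if config.structure_veto == "any":
        structured = record.cf_structured | record.gr_structured
    else:
        structured = record.cf_structured & record.gr_structured
    ok = record.disorder & ~structured

    runs: list[Interval] = []
    start = None
    gap = 0
    for pos in range(record.length):
        if ok[pos]:
            if start is None:
                start = pos
            end = pos
            gap = 0
        elif start is not None:
            gap += 1
            if gap > config.max_gap:
                runs.append((start + 1, end + 1))
                start, gap = None, 0
    if start is not None:
        runs.append((start + 1, end + 1))
    return runs


def classify_net(
    record: NETRecord, config: ClassifierConfig | None = None
) -> ClassificationResult:
    """Apply the eligibility rule to one NET.

    A qualifying NLS is a hit scoring at least the threshold and lying
    inside an extraluminal domain.  A qualifying ID run is a maximal run of
    disorder-called, structure-free residues of at least the minimum length,
    wholly inside one extraluminal domain.  The arrangement check requires,
    within a single extraluminal domain, a qualifying ID run between the
    membrane-proximal end of a qualifying NLS and the domain edge facing the
    nearest TM segment.  Category "Both" requires all three; a record with
    both features but a failing arrangement is reported as NLS-only (the
    receptor site remains functional; the mis-placed ID run does not aid
    central-channel transit).
    """
    config = config or ClassifierConfig()
    q_nls = tuple(
        (iv, score)
        for iv, score in record.nls_hits
        if score >= config.nls_threshold
        and any(_contains(dom, iv) for dom in record.extraluminal_domains)
    )
    q_runs = tuple(
        run
        for run in _id_runs(record, config)
        if (run[1] - run[0] + 1) >= config.min_id_length
        and any(_contains(dom, run) for dom in record.extraluminal_domains)
    )

    arrangement = False
    for dom in record.extraluminal_domains:
        dom_nls = [iv for iv, _ in q_nls if _contains(dom, iv)]
        dom_runs = [run for run in q_runs if _contains(dom, run)]
        if not dom_nls or not dom_runs:
            continue
        # TM segments flanking this domain define the membrane-facing side(s)
        tm_after = any(tm[0] == dom[1] + 1 for tm in record.tm_segments)
        tm_before = any(tm[1] == dom[0] - 1 for tm in record.tm_segments)
        for nls in dom_nls:
            for run in dom_runs:
                if tm_after and nls[1] < run[0] and run[1] <= dom[1]:
                    arrangement = True  # NLS .. ID run .. TM at C-side
                if tm_before and run[1] < nls[0] and dom[0] <= run[0]:
                    arrangement = True  # TM at N-side .. ID run .. NLS
    has_nls = bool(q_nls)
    has_id = bool(q_runs)
    if has_nls and has_id and arrangement:
        category = "Both"
    elif has_nls:
        category = "NLS-only"
    elif has_id:
        category = "ID-only"
    else:
        category = "Neither"
    longest = max((run[1] - run[0] + 1 for run in q_runs), default=0)
    return ClassificationResult(
        id=record.id,
        localization_class=record.localization_class,
        category=category,
        qualifying_nls=q_nls,
        qualifying_id_runs=q_runs,
        arrangement_ok=arrangement,
        reach_nm=reach_nm(longest, config),
    )


def cohort_summary(results: list[ClassificationResult]) -> pd.DataFrame:
    """Per-localization-class counts and fractions in each category.

    Fractions are exact; round percentages to whole numbers at reporting.
    """
    if not results:
        raise ValueError("empty result list")
    rows = []
    frame = pd.DataFrame(
        {
            "class": [r.localization_class for r in results],
            "category": [r.category for r in results],
        }
    )
    for cls, grp in frame.groupby("class"):
        n = len(grp)
        for cat in CATEGORIES:
            count = int((grp["category"] == cat).sum())
            rows.append(
                {
                    "class": cls,
                    "category": cat,
                    "count": count,
                    "n": n,
                    "fraction": count / n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV annotation I/O

MANDATORY_NET_COLUMNS = (
    "id",
    "class",
    "length",
    "tm_segments",
    "extraluminal_domains",
    "nls_hits",
    "disorder_runs",
    "cf_structured_runs",
    "gr_structured_runs",
)


def _parse_intervals(text: str) -> tuple[Interval, ...]:
    text = (text or "").strip()
    if not text or text == ".":
        return ()
    out = []
    for part in text.split(";"):
        lo, hi = part.split("-")
        out.append((int(lo), int(hi)))
    return tuple(out)


def _parse_nls(text: str) -> tuple[tuple[Interval, float], ...]:
    text = (text or "").strip()
    if not text or text == ".":
        return ()
    out = []
    for part in text.split(";"):
        span, score = part.split(":")
        lo, hi = span.split("-")
        out.append(((int(lo), int(hi)), float(score)))
    return tuple(out)


def _runs_to_track(runs: tuple[Interval, ...], length: int) -> np.ndarray:
    track = np.zeros(length, dtype=bool)
    for lo, hi in runs:
        if not (1 <= lo <= hi <= length):
            raise ValueError(f"interval {(lo, hi)} outside [1, {length}]")
        track[lo - 1 : hi] = True
    return track


def _track_to_runs(track: np.ndarray) -> str:
    runs = []
    start = None
    for pos, flag in enumerate(track):
        if flag and start is None:
            start = pos
        elif not flag and start is not None:
            runs.append(f"{start + 1}-{pos}")
            start = None
    if start is not None:
        runs.append(f"{start + 1}-{len(track)}")
    return ";".join(runs) or "."


def parse_net_annotations(path: str | Path) -> list[NETRecord]:
    """Read NET annotation records from a TSV file.

    Interval columns are semicolon-separated ``start-end`` spans (1-based
    inclusive; ``.`` or empty for none); ``nls_hits`` entries are
    ``start-end:score``.  Malformed rows are skipped with a warning naming
    the line number; missing mandatory columns raise ``ValueError``.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MANDATORY_NET_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[NETRecord] = []
    for idx, row in table.iterrows():
        line_no = idx + 2  # 1-based, after the header line
        try:
            length = int(row["length"])
            records.append(
                NETRecord(
                    id=row["id"],
                    localization_class=row["class"],
                    length=length,
                    tm_segments=_parse_intervals(row["tm_segments"]),
                    extraluminal_domains=_parse_intervals(row["extraluminal_domains"]),
                    nls_hits=_parse_nls(row["nls_hits"]),
                    disorder=_runs_to_track(_parse_intervals(row["disorder_runs"]), length),
                    cf_structured=_runs_to_track(
                        _parse_intervals(row["cf_structured_runs"]), length
                    ),
                    gr_structured=_runs_to_track(
                        _parse_intervals(row["gr_structured_runs"]), length
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            warnings.warn(f"rejected annotation row at line {line_no}: {exc}",
                          stacklevel=2)
    return records


def write_net_annotations(records: list[NETRecord], path: str | Path) -> None:
    """Write NET records back to the TSV dialect read by the parser."""
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "class": rec.localization_class,
                "length": rec.length,
                "tm_segments": ";".join(f"{a}-{b}" for a, b in rec.tm_segments) or ".",
                "extraluminal_domains": ";".join(
                    f"{a}-{b}" for a, b in rec.extraluminal_domains
                )
                or ".",
                "nls_hits": ";".join(
                    f"{a}-{b}:{score:g}" for (a, b), score in rec.nls_hits
                )
                or ".",
                "disorder_runs": _track_to_runs(rec.disorder),
                "cf_structured_runs": _track_to_runs(rec.cf_structured),
                "gr_structured_runs": _track_to_runs(rec.gr_structured),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
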