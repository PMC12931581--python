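"""Rare/unique OTU classification and molecular artefact screening.

Artefact screening follows three sequence rules applied to the global
alignment of each OTU against its best-matching reference:

(i)   a long indel — any gap run longer than 20 bases anywhere;
(ii)  more than one single-nucleotide indel inside a fixed 200-base window
      (the conserved 5.8S + ITS2-start region in real fungal amplicons);
(iii) excess divergence — p-distance strictly above 2%.

Alignment is pairwise global with affine gap penalties (the p-distance to
the best reference serves as a branch-length proxy).  The synthetic
alignment generator plants these signatures with recorded ground truth so
screening performance is exactly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from ._rng import substream
from .labsim import ReadTable

__all__ = [
    "AlignedPair",
    "classify_rare",
    "classify_unique",
    "align_global",
    "screen_artefacts",
    "pooling_artefact_report",
    "make_synthetic_alignment",
    "write_fasta",
]

RARE_THRESHOLD = 0.0005  # relative abundance <= 0.05% of total reads
DNA = "ACGT"
IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class AlignedPair:
    """A global query/reference alignment with gap bookkeeping.

    ``gap_runs`` lists (row, start_column, length) with row 'query' (gap in
    the query = deletion) or 'reference' (insertion).  ``p_distance`` is
    mismatches over compared (both-non-gap) columns.
    """

    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_reference):
            raise ValueError("aligned strings differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_query)

    @property
    def gap_runs(self) -> list[tuple[str, int, int]]:
        runs = []
        for row, s in (("query", self.aligned_query),
                       ("reference", self.aligned_reference)):
            start = None
            for i, c in enumerate(s + "x"):
                if c == "-" and start is None:
                    start = i
                elif c != "-" and start is not None:
                    runs.append((row, start, i - start))
                    start = None
        return runs

    @property
    def p_distance(self) -> float:
        q, r = self.aligned_query, self.aligned_reference
        compared = mismatch = 0
        for a, b in zip(q, r):
            if a != "-" and b != "-":
                compared += 1
                if a != b:
                    mismatch += 1
        if compared == 0:
            return 0.0
        return mismatch / compared

    def reference_positions(self) -> np.ndarray:
        """Reference coordinate of each alignment column (gaps get the
        position of the next reference base)."""
        pos = np.empty(self.length, dtype=int)
        p = 0
        for i, c in enumerate(self.aligned_reference):
            pos[i] = p
            if c != "-":
                p += 1
        return pos


def _check_sequence(seq: str, allow_iupac: bool) -> str:
    s = seq.upper()
    alphabet = IUPAC if allow_iupac else set(DNA)
    bad = set(s) - alphabet
    if bad:
        raise ValueError(f"non-ACGT symbols {sorted(bad)} in sequence")
    if not s:
        raise ValueError("empty sequence")
    return s


def align_global(
    query: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    query_id: str = "query",
    reference_id: str = "reference",
    allow_iupac: bool = False,
) -> AlignedPair:
    """Optimal global alignment with affine gap scoring.

    The first optimal alignment under Biopython's deterministic traceback
    is returned, so repeated calls agree exactly.
    """
    q = _check_sequence(query, allow_iupac)
    r = _check_sequence(reference, allow_iupac)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(q, r)[0]
    return AlignedPair(
        query_id=query_id,
        reference_id=reference_id,
        aligned_query=str(aln[0]),
        aligned_reference=str(aln[1]),
        score=float(aln.score),
    )


def screen_artefacts(
    pair: AlignedPair,
    window_start: int,
    window_length: int = 200,
    long_indel_min: int = 21,
    max_single_nt_indels: int = 1,
    divergence_max: float = 0.02,
) -> set[str]:
    """Apply the three artefact rules; returns the subset of flags raised.

    ``window_start`` is in reference coordinates.  Rule (i) counts any gap
    run of >= ``long_indel_min`` bases anywhere; rule (ii) counts gap runs
    of exactly one base whose column maps inside the window and fires when
    their number exceeds ``max_single_nt_indels``; rule (iii) is a strict
    inequality on p-distance.
    """
    ref_len = sum(1 for c in pair.aligned_reference if c != "-")
    if window_length > ref_len:
        raise ValueError("window longer than the aligned reference")
    flags: set[str] = set()
    runs = pair.gap_runs
    if any(length >= long_indel_min for _, _, length in runs):
        flags.add("long_indel")
    ref_pos = pair.reference_positions()
    in_window = 0
    for _, start, length in runs:
        if length == 1 and window_start <= ref_pos[start] < window_start + window_length:
            in_window += 1
    if in_window > max_single_nt_indels:
        flags.add("multi_indel_window")
    if pair.p_distance > divergence_max:
        flags.add("excess_divergence")
    return flags


# ---------------------------------------------------------------------------
# table-level classification


def classify_rare(
    table: ReadTable, threshold: float = RARE_THRESHOLD, stratum: str = "site"
):
    """Rare OTU flags: reads / grand-total reads <= threshold (inclusive).

    With ``stratum='site'`` (default) the denominator is each site's total
    reads and the result is an OTU x site boolean frame (False where the
    OTU is absent from the site); ``stratum='all'`` returns one Series over
    the whole table.
    """
    total = table.counts.values.sum()
    if total <= 0:
        raise ValueError("empty table")
    if stratum == "all":
        share = table.counts.sum(axis=0) / total
        return share <= threshold
    if stratum != "site":
        raise ValueError("stratum must be 'site' or 'all'")
    out = {}
    for site, meta in table.sample_meta.groupby("site"):
        sub = table.counts.loc[meta.index]
        tot = sub.values.sum()
        sums = sub.sum(axis=0)
        out[site] = (sums > 0) & (sums / tot <= threshold)
    return pd.DataFrame(out)


def classify_unique(table: ReadTable, site: str) -> pd.Series:
    """Design name for OTUs detected at the site by exactly one design
    (across all strategies), NaN otherwise."""
    meta = table.sample_meta
    at_site = meta["site"] == site
    designs = meta.loc[at_site, "design"].unique()
    if len(designs) < 2:
        raise ValueError(f"site {site} has a single design")
    presence = {}
    for d in designs:
        rows = table.counts.loc[(at_site & (meta["design"] == d)).values]
        presence[d] = rows.sum(axis=0) > 0
    pres = pd.DataFrame(presence)
    n_designs = pres.sum(axis=1)
    unique = pres.idxmax(axis=1).where(n_designs == 1)
    return unique[n_designs > 0]


def pooling_artefact_report(
    table: ReadTable,
    pe_results: Sequence | None = None,
    rare_threshold: float = RARE_THRESHOLD,
) -> pd.DataFrame:
    """Rare / unique / artefact accounting per (site, strategy).

    Emits, per stratum: OTU, artefact, rare, rare-artefact, unique and
    unique-artefact counts plus the proportions artefact/OTUs, rare/OTUs
    and rare-artefacts/rare (NaN when a denominator is zero).  When
    pooling-effect results are supplied, strata are additionally split by
    the PE direction (> 1 vs < 1 at q=0, full summary depth) of their
    designs.
    """
    is_artefact = table.otu_registry["origin"] == "artefact"
    rare = classify_rare(table, rare_threshold, stratum="site")
    meta = table.sample_meta

    pe_dir: dict[tuple[str, str, str], str] = {}
    if pe_results is not None:
        for r in pe_results:
            if r.q == 0 and r.depth_fraction == 1.0 and np.isfinite(r.pe):
                pe_dir[(r.site_id, r.design_name, r.strategy)] = (
                    "PE>1" if r.pe > 1 else "PE<1"
                )

    recs = []
    for (site, strategy), sub_meta in meta.groupby(["site", "strategy"]):
        unique = classify_unique(table, site) if (
            meta.loc[meta["site"] == site, "design"].nunique() > 1
        ) else pd.Series(dtype=object)
        directions = sorted(
            {pe_dir.get((site, d, strategy), "")
             for d in sub_meta["design"].unique()}
        )
        for direction in directions:
            designs = [
                d for d in sub_meta["design"].unique()
                if pe_dir.get((site, d, strategy), "") == direction
            ]
            rows = table.counts.loc[
                sub_meta.index[sub_meta["design"].isin(designs)]
            ]
            detected = rows.sum(axis=0) > 0
            otus = detected.index[detected]
            n = len(otus)
            art = is_artefact.reindex(otus, fill_value=False)
            rare_site = (
                rare[site].reindex(otus, fill_value=False)
                if site in rare else pd.Series(False, index=otus)
            )
            uniq = otus.isin(unique.dropna().index)
            n_art = int(art.sum())
            n_rare = int(rare_site.sum())
            n_rare_art = int((art & rare_site).sum())
            n_uniq = int(uniq.sum())
            n_uniq_art = int((art.values & uniq).sum())
            recs.append(
                dict(
                    site=site, strategy=strategy, pe_direction=direction,
                    n_otus=n, n_artefacts=n_art, n_rare=n_rare,
                    n_rare_artefacts=n_rare_art, n_unique=n_uniq,
                    n_unique_artefacts=n_uniq_art,
                    prop_artefact=n_art / n if n else np.nan,
                    prop_rare=n_rare / n if n else np.nan,
                    prop_rare_artefact=(n_rare_art / n_rare
                                        if n_rare else np.nan),
                )
            )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# synthetic sequence fixtures

WINDOW_START = 200
WINDOW_LENGTH = 200
SEQ_LENGTH = 600
ARTEFACT_KINDS = ("long_indel", "multi_indel_window", "excess_divergence")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, length)])


def _mutate(seq: str, n_subs: int, rng: np.random.Generator,
            lo: int = 0, hi: int | None = None) -> str:
    """Apply exactly n_subs substitutions at distinct positions in [lo, hi)."""
    hi = len(seq) if hi is None else hi
    s = list(seq)
    pos = rng.choice(np.arange(lo, hi), size=n_subs, replace=False)
    for p in pos:
        s[p] = rng.choice([b for b in DNA if b != s[p]])
    return "".join(s)


def make_synthetic_alignment(
    registry: pd.DataFrame, seed: int = 0
) -> dict:
    """Generate OTU + reference sequences with planted artefact signatures.

    Biological OTUs are near-identical copies of their species' reference
    (substitution count capped well below the 2% divergence rule).
    Artefact OTUs carry one signature chosen uniformly: a >20-base
    deletion, two single-base deletions inside the screening window, or
    > 2% divergence.  Returns dict with ``otus`` (id -> sequence),
    ``references`` (id -> sequence), ``best_reference`` (otu -> ref id),
    ``truth`` (otu -> planted signature or 'biological') and the window
    coordinates.  Deterministic given ``seed``.
    """
    rng = substream(seed, "synthaln")
    parents = registry["parent"].unique()
    refs = {
        f"ref_{p}": _random_seq(substream(seed, "ref", p), SEQ_LENGTH)
        for p in parents
    }
    ref_ids = list(refs)
    otus: dict[str, str] = {}
    best_ref: dict[str, str] = {}
    truth: dict[str, str] = {}
    max_bio_subs = int(0.015 * SEQ_LENGTH)  # stays under the 2% rule
    for otu_id, row in registry.iterrows():
        if row["origin"] == "biological":
            rid = f"ref_{row['parent']}"
        else:
            rid = ref_ids[rng.integers(0, len(ref_ids))]
        base = refs[rid]
        r = substream(seed, "otu", otu_id)
        if row["origin"] == "biological":
            n_subs = min(int(r.binomial(SEQ_LENGTH, 0.005)), max_bio_subs)
            seq = _mutate(base, n_subs, r)
            truth[otu_id] = "biological"
        else:
            kind = ARTEFACT_KINDS[r.integers(0, len(ARTEFACT_KINDS))]
            if kind == "long_indel":
                length = int(r.integers(21, 41))
                start = int(r.integers(50, SEQ_LENGTH - length - 50))
                seq = base[:start] + base[start + length:]
            elif kind == "multi_indel_window":
                p1 = WINDOW_START + int(r.integers(20, 60))
                p2 = WINDOW_START + int(r.integers(120, 180))
                seq = base[:p1] + base[p1 + 1:p2] + base[p2 + 1:]
            else:
                n_subs = int(round(0.035 * SEQ_LENGTH))
                seq = _mutate(base, n_subs, r)
            truth[otu_id] = kind
        otus[otu_id] = seq
        best_ref[otu_id] = rid
    return dict(
        otus=otus, references=refs, best_reference=best_ref,
        truth=pd.Series(truth, name="truth"),
        window_start=WINDOW_START, window_length=WINDOW_LENGTH,
    )


def write_fasta(records: Mapping[str, str], path, window: tuple[int, int] | None = None) -> None:
    """Plain FASTA; the screening window is carried in each header."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            header = f">{name}"
            if window is not None:
                header += f" window={window[0]}:{window[0] + window[1]}"
            fh.write(header + "\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
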