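"""Consensus-mutagenesis candidate calling from a multiple sequence alignment.

Consensus mutagenesis stabilizes a protein by substituting residues that are
under-represented among close homologs with the residue most frequent at that
alignment column.  Given a gapped MSA containing the target ("reference")
sequence and a set of homologs, this module

* filters homologs by pairwise identity to the reference,
* tallies per-column residue counts over the homologs,
* emits substitution proposals ("consensus calls") at columns where the
  wildtype residue is rare and a clear majority residue exists, and
* exports a signed differential-logo matrix (non-wildtype residue frequencies
  up, wildtype frequency deficit down) for visualisation.

Alignment construction itself is out of scope: the MSA is read from FASTA as
produced by external aligners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentFormatError,
    EmptyHomologSetError,
    EmptyInputError,
    MissingReferenceError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
VALID_SYMBOLS = set(AMINO_ACIDS) | {GAP, UNKNOWN}


@dataclass(frozen=True)
class Alignment:
    """A gapped MSA with a designated reference sequence.

    All sequences have equal length and use one-letter amino-acid codes,
    ``-`` for gaps and ``X`` for unknown residues (treated as missing data).
    """

    records: tuple[tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentFormatError("sequences are empty")
        ids = [rid for rid, _ in self.records]
        if self.reference_id not in ids:
            raise MissingReferenceError(
                f"reference {self.reference_id!r} not among record ids"
            )
        if len(ids) != len(set(ids)):
            raise AlignmentFormatError("duplicate record identifiers")
        for rid, seq in self.records:
            bad = set(seq) - VALID_SYMBOLS
            if bad:
                raise AlignmentFormatError(
                    f"record {rid!r} contains invalid symbols {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def reference_seq(self) -> str:
        return dict(self.records)[self.reference_id]

    @property
    def homolog_records(self) -> list[tuple[str, str]]:
        return [(rid, s) for rid, s in self.records if rid != self.reference_id]

    @property
    def n_homologs(self) -> int:
        return len(self.records) - 1


@dataclass(frozen=True)
class ColumnProfile:
    """Residue tally for one alignment column where the reference is non-gap.

    ``counts`` covers homolog rows only (the reference does not vote for
    itself); gaps and ``X`` are tracked in ``n_missing`` and excluded from
    frequency denominators.
    """

    column_index: int          # 0-based alignment coordinate
    ref_position: int          # 1-based ungapped position in the reference
    ref_residue: str
    counts: dict[str, int] = field(compare=False)
    n_missing: int = 0         # homolog gaps + unknowns at this column
    coverage: float = 1.0      # fraction of homologs with a residue here

    @property
    def n_observed(self) -> int:
        return sum(self.counts.values())

    def frequency(self, residue: str) -> float:
        n = self.n_observed
        return self.counts.get(residue, 0) / n if n else 0.0

    def modal_residue(self) -> tuple[str, float] | None:
        """Most frequent homolog residue; ties broken by count then alphabet."""
        if not self.counts:
            return None
        residue = min(self.counts, key=lambda r: (-self.counts[r], r))
        return residue, self.frequency(residue)


@dataclass(frozen=True)
class ConsensusCall:
    """A proposed consensus substitution at one reference position."""

    ref_position: int
    wt_residue: str
    proposed_residue: str
    wt_frequency: float
    consensus_frequency: float
    coverage: float
    in_structure: bool | None = None  # set by exclude_near_active_site

    def __post_init__(self) -> None:
        if self.proposed_residue == self.wt_residue:
            raise ValueError("proposed residue equals wildtype residue")
        if self.consensus_frequency < self.wt_frequency:
            raise ValueError("consensus frequency below wildtype frequency")

    @property
    def mutation(self) -> str:
        return f"{self.wt_residue}{self.ref_position}{self.proposed_residue}"


def read_alignment(path, reference_id: str) -> Alignment:
    """Read a gapped FASTA MSA; record order is preserved.

    Raises ``EmptyInputError`` for an empty file, ``AlignmentFormatError``
    for ragged or invalid sequences, ``MissingReferenceError`` if
    ``reference_id`` is absent.
    """
    records = [(r.id, str(r.seq).upper().replace(".", GAP))
               for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment(tuple(records), reference_id)


def write_alignment(aln: Alignment, path) -> None:
    """Canonical FASTA writer (one line per sequence)."""
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns where both are non-gap.

    ``X`` counts as missing and is excluded from the denominator, like gaps.
    Returns 0.0 (with a warning) when no column is shared.
    """
    if len(a) != len(b):
        raise AlignmentFormatError(
            f"sequence lengths differ: {len(a)} vs {len(b)}"
        )
    missing = (GAP, UNKNOWN)
    shared = [(x, y) for x, y in zip(a, b)
              if x not in missing and y not in missing]
    if not shared:
        warnings.warn("no shared non-gap columns; identity undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    return sum(x == y for x, y in shared) / len(shared)


def filter_homologs(aln: Alignment, min_identity: float = 0.60) -> Alignment:
    """Keep the reference plus homologs with identity strictly above threshold.

    Columns that become all-gap after filtering are removed; reference
    numbering is unaffected because the reference row is never touched.
    """
    ref = aln.reference_seq
    kept = [(rid, seq) for rid, seq in aln.records
            if rid == aln.reference_id or pairwise_identity(ref, seq) > min_identity]
    if len(kept) < 2:
        raise EmptyHomologSetError(
            f"no homolog exceeds identity {min_identity} to the reference"
        )
    seqs = np.array([list(s) for _, s in kept])
    not_all_gap = ~(seqs == GAP).all(axis=0)
    trimmed = ["".join(row) for row in seqs[:, not_all_gap]]
    return Alignment(tuple((rid, s) for (rid, _), s in zip(kept, trimmed)),
                     aln.reference_id)


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """One profile per column where the reference is non-gap.

    Counts are tallied over homolog rows only; ``ref_position`` increments
    only at reference non-gap columns (1-based, matching mutation
    nomenclature such as E75P).
    """
    ref = aln.reference_seq
    homologs = [seq for _, seq in aln.homolog_records]
    n_hom = len(homologs)
    profiles: list[ColumnProfile] = []
    ref_pos = 0
    for col in range(aln.length):
        if ref[col] == GAP:
            continue
        ref_pos += 1
        counts: dict[str, int] = {}
        missing = 0
        for seq in homologs:
            sym = seq[col]
            if sym in (GAP, UNKNOWN):
                missing += 1
            else:
                counts[sym] = counts.get(sym, 0) + 1
        coverage = (n_hom - missing) / n_hom if n_hom else 0.0
        profiles.append(ColumnProfile(
            column_index=col, ref_position=ref_pos, ref_residue=ref[col],
            counts=counts, n_missing=missing, coverage=coverage,
        ))
    return profiles


def call_consensus(
    profiles: list[ColumnProfile],
    wt_max_freq: float = 0.30,
    consensus_min_freq: float = 0.50,
    min_coverage: float = 0.70,
) -> list[ConsensusCall]:
    """Emit a consensus call wherever the wildtype residue is under-represented.

    A call is made iff coverage >= ``min_coverage``, the wildtype frequency is
    <= ``wt_max_freq``, the modal non-gap homolog residue differs from
    wildtype, and its frequency is >= ``consensus_min_freq``.  Frequencies are
    over non-gap, non-``X`` homolog residues.  Modal ties are broken by higher
    count then alphabetical order, so output is deterministic.
    """
    for name, val in (("wt_max_freq", wt_max_freq),
                      ("consensus_min_freq", consensus_min_freq),
                      ("min_coverage", min_coverage)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    calls = []
    for p in profiles:
        if p.coverage < min_coverage or not p.counts:
            continue
        modal = p.modal_residue()
        assert modal is not None
        res, freq = modal
        wt_freq = p.frequency(p.ref_residue)
        if res != p.ref_residue and wt_freq <= wt_max_freq and freq >= consensus_min_freq:
            calls.append(ConsensusCall(
                ref_position=p.ref_position, wt_residue=p.ref_residue,
                proposed_residue=res, wt_frequency=wt_freq,
                consensus_frequency=freq, coverage=p.coverage,
            ))
    return calls


def differential_logo_matrix(profiles: list[ColumnProfile]) -> pd.DataFrame:
    """Signed per-position height table for a differential sequence logo.

    Rows are reference positions, columns the 20 amino acids.  Non-wildtype
    residues get their homolog frequency as a positive height; the wildtype
    residue's cell holds the negative frequency deficit ``-(1 - f_wt)``,
    giving the downward axis extent.  Fully conserved columns are all zero.
    """
    mat = pd.DataFrame(
        0.0, index=[p.ref_position for p in profiles], columns=list(AMINO_ACIDS)
    )
    mat.index.name = "ref_position"
    for p in profiles:
        if not p.counts:
            continue
        for res in p.counts:
            if res != p.ref_residue:
                mat.at[p.ref_position, res] = p.frequency(res)
        mat.at[p.ref_position, p.ref_residue] = -(1.0 - p.frequency(p.ref_residue))
    return mat


def exclude_near_active_site(
    calls: list[ConsensusCall],
    structure,
    active_site_residues: list[int],
    radius: float,
    chain: str | None = None,
) -> list[ConsensusCall]:
    """Drop calls whose Calpha lies strictly within ``radius`` (angstrom) of any
    active-site residue Calpha.

    Stabilizing substitutions are restricted to positions outside the active
    site; ``radius`` 0 therefore removes nothing.  Structure residue numbering
    must match reference numbering.  Calls at positions absent from the
    structure are retained with a warning and flagged ``in_structure=False``.
    """
    from dataclasses import replace

    ca = structure.ca_lookup(chain)
    site = np.array([ca[r] for r in active_site_residues if r in ca])
    missing_site = [r for r in active_site_residues if r not in ca]
    if missing_site:
        warnings.warn(f"active-site residues missing from structure: "
                      f"{missing_site}", stacklevel=2)
    kept = []
    for call in calls:
        if call.ref_position not in ca:
            warnings.warn(f"call position {call.ref_position} absent from "
                          "structure; retained", stacklevel=2)
            kept.append(replace(call, in_structure=False))
            continue
        pos = np.asarray(ca[call.ref_position])
        if site.size and float(np.min(np.linalg.norm(site - pos, axis=1))) < radius:
            continue
        kept.append(replace(call, in_structure=True))
    return kept


def calls_to_frame(calls: list[ConsensusCall]) -> pd.DataFrame:
    """Tabulate calls with the CSV header used by the CLI."""
    return pd.DataFrame(
        [(c.ref_position, c.wt_residue, c.proposed_residue,
          c.wt_frequency, c.consensus_frequency, c.coverage) for c in calls],
        columns=["ref_position", "wt", "proposed", "wt_freq", "cons_freq",
                 "coverage"],
    )
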