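"""Ortholog sequence comparison for synuclein family proteins.

Pairwise global alignment (Needleman-Wunsch with affine gaps, BLOSUM62,
gap open 10 / extend 0.5) with percent identity and similarity over the
full sequence or domain windows (N-terminal 1-95, NAC 60-95, the
anti-pan-synuclein epitope 11-26), and sliding-window charge profiles
(K/R = +1, D/E = -1, H = +0.5 by the common physiological convention,
configurable to 0).

The canonical human synuclein proteins (alpha, beta, gamma — the CDS
products of the transcripts NM_000345.4, NM_001001502.3 and NM_003087.3)
ship with the package.  The lamprey gamma-synuclein protein (GenBank
JN544525.1) is not redistributed here; it is fetched from NCBI on demand
when network access is available.  A clearly labelled *synthetic* lamprey
stand-in ships for offline pipeline demonstrations only — its residues are
randomly perturbed from human gamma-synuclein and carry no biological
meaning.
"""

from __future__ import annotations

import math
import re
import urllib.error
import urllib.request
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import ValidationError

__all__ = [
    "ProteinSequence",
    "AlignmentResult",
    "ChargeProfile",
    "read_fasta",
    "write_fasta",
    "global_align",
    "domain_slice",
    "charge_profile",
    "load_human_synucleins",
    "load_lamprey_gamma_synuclein",
    "load_lamprey_standin",
    "fetch_ncbi_protein",
    "conservation_report",
    "DOMAINS",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

#: Domain windows (1-based inclusive) used in synuclein conservation work.
DOMAINS = {
    "full": None,
    "n_terminal": (1, 95),
    "nac": (60, 95),
    "epitope": (11, 26),
}

#: Residue charges at physiological pH; histidine at +0.5 follows the
#: common convention of sliding-window charge tools.
RESIDUE_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.5}

LAMPREY_ACCESSION = "JN544525.1"
_NCBI_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta_cds_aa&retmode=text"
)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: accession-style id plus one-letter residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = [
            (i + 1, r) for i, r in enumerate(self.residues) if r not in VALID_RESIDUES
        ]
        if bad:
            pos, res = bad[0]
            raise ValidationError(
                f"sequence {self.id!r}: illegal residue {res!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings must have equal length")
        if self.identity_pct > self.similarity_pct + 1e-9:
            raise ValidationError("identity cannot exceed similarity")


@dataclass(frozen=True)
class ChargeProfile:
    window: int
    values: np.ndarray


def read_fasta(path: Union[str, Path]) -> list[ProteinSequence]:
    """Read protein sequences from FASTA; whitespace stripped, uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        residues = re.sub(r"\s+", "", str(rec.seq)).upper()
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        out.append(ProteinSequence(id=rec.id, residues=residues, description=desc))
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length L is penalized gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    identity_denominator: str = "alignment",
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences with affine gaps.

    ``identity_pct`` is the fraction of identical columns over the
    alignment length (or over the shorter input with
    ``identity_denominator='shorter'``, matching the other common
    convention); ``similarity_pct`` additionally counts aligned residue
    pairs with a positive substitution score.
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    sub = aligner.substitution_matrix
    for seq in (a, b):
        missing = set(seq.residues) - set(sub.alphabet)
        if missing:
            raise ValidationError(
                f"sequence {seq.id!r}: residues {sorted(missing)} absent from {matrix}"
            )
    aln = aligner.align(a.residues, b.residues)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    n_cols = len(aligned_a)
    identical = 0
    similar = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            identical += 1
            similar += 1
        elif sub[x, y] > 0:
            similar += 1
    if identity_denominator == "alignment":
        denom = n_cols
    elif identity_denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValidationError(f"unknown identity_denominator {identity_denominator!r}")
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity_pct=100.0 * identical / denom,
        similarity_pct=100.0 * similar / denom,
    )


def domain_slice(seq: ProteinSequence, start: int, end: int) -> ProteinSequence:
    """Inclusive 1-based slice of a sequence (e.g. the N-terminal 1-95)."""
    if not (1 <= start <= end <= len(seq)):
        raise ValidationError(
            f"slice {start}-{end} out of range for {seq.id!r} (length {len(seq)})"
        )
    return ProteinSequence(
        id=f"{seq.id}/{start}-{end}",
        residues=seq.residues[start - 1 : end],
        description=seq.description,
    )


def charge_profile(
    seq: ProteinSequence, window: int = 5, histidine_charge: float = 0.5
) -> ChargeProfile:
    """Sliding-window mean residue charge with centered windows.

    Windows must be odd; the profile has one value per center position and
    the ends are truncated (length ``L - window + 1``).
    """
    if window % 2 == 0 or window < 1:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    if window > len(seq):
        raise ValidationError(f"window {window} exceeds sequence length {len(seq)}")
    charges = {**RESIDUE_CHARGE, "H": histidine_charge}
    vals = np.array([charges.get(r, 0.0) for r in seq.residues], dtype=float)
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    return ChargeProfile(window=window, values=means)


# ---------------------------------------------------------------------------
# reference sequences


def _data_path(name: str):
    return resources.files("synmorph").joinpath("data", name)


def load_human_synucleins() -> dict[str, ProteinSequence]:
    """The canonical human alpha-, beta- and gamma-synuclein proteins."""
    with resources.as_file(_data_path("human_synucleins.fasta")) as p:
        seqs = read_fasta(p)
    keys = {"alpha": "NM_000345.4", "beta": "NM_001001502.3", "gamma": "NM_003087.3"}
    by_id = {s.id: s for s in seqs}
    return {name: by_id[acc] for name, acc in keys.items()}


def load_lamprey_standin() -> ProteinSequence:
    """The synthetic lamprey gamma-synuclein stand-in (offline demos only).

    Randomly perturbed from human gamma-synuclein; NOT the JN544525.1
    protein, and not suitable for any biological conclusion.
    """
    with resources.as_file(_data_path("lamprey_gamma_synuclein_synthetic.fasta")) as p:
        return read_fasta(p)[0]


def fetch_ncbi_protein(accession: str, timeout: float = 10.0) -> ProteinSequence:
    """Fetch the CDS protein of a GenBank nucleotide accession from NCBI."""
    url = _NCBI_EFETCH.format(acc=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise ConnectionError(f"could not fetch {accession} from NCBI: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValidationError(f"unexpected efetch response for {accession}")
    residues = "".join(lines[1:]).replace("*", "").upper()
    return ProteinSequence(id=accession, residues=residues, description=lines[0][1:])


def load_lamprey_gamma_synuclein(
    cache: Optional[Union[str, Path]] = None, timeout: float = 10.0
) -> ProteinSequence:
    """The genuine lamprey gamma-synuclein protein (GenBank JN544525.1).

    Looks for a locally cached FASTA (``cache`` path, or a ``JN544525.1.fasta``
    placed in the package data directory) and otherwise fetches from NCBI.
    Raises ``ConnectionError`` when neither a cache nor network is available;
    the synthetic stand-in is deliberately NOT substituted here.
    """
    candidates = []
    if cache is not None:
        candidates.append(Path(cache))
    pkg_cache = _data_path(f"{LAMPREY_ACCESSION}.fasta")
    try:
        with resources.as_file(pkg_cache) as p:
            if p.exists():
                candidates.append(p)
    except FileNotFoundError:
        pass
    for c in candidates:
        if Path(c).exists():
            seq = read_fasta(c)[0]
            return ProteinSequence(
                id=LAMPREY_ACCESSION, residues=seq.residues, description=seq.description
            )
    return fetch_ncbi_protein(LAMPREY_ACCESSION, timeout=timeout)


def conservation_report(
    a: ProteinSequence,
    b: ProteinSequence,
    regions: Optional[dict] = None,
    **align_kwargs,
) -> dict[str, dict[str, float]]:
    """Identity/similarity of two sequences over the standard domain windows.

    Windows extending beyond either sequence are clipped to its length.
    """
    regions = DOMAINS if regions is None else regions
    out: dict[str, dict[str, float]] = {}
    for name, span in regions.items():
        if span is None:
            sa, sb = a, b
        else:
            start, end = span
            sa = domain_slice(a, start, min(end, len(a)))
            sb = domain_slice(b, start, min(end, len(b)))
        res = global_align(sa, sb, **align_kwargs)
        out[name] = {
            "identity_pct": res.identity_pct,
            "similarity_pct": res.similarity_pct,
            "score": res.score,
        }
    return out
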