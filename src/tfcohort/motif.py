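"""Promoter scanning with position weight matrices and target-propensity scoring.

A PWM describes the base preferences of a transcription factor across the
positions of its binding site.  Scanning slides the matrix along both strands
of a promoter window and scores every offset with the information-weighted
matrix similarity score (MSS) and core similarity score (CSS), both normalised
to [0, 1] between the worst and best attainable scores.  Offsets passing both
cutoffs are reported as putative binding sites.

The per-gene *target propensity* summarises predicted binding-site density:
the mean, over a gene's alternative promoters, of the promoter's site density
relative to the global background density (total sites / total bases over all
promoters).  A gene whose promoters look like random background therefore has
propensity ~1, and a value of 5 reads as "five-fold background site density".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as _bio_motifs
from Bio.motifs import transfac as _transfac

__all__ = [
    "PWM",
    "Promoter",
    "PromoterSet",
    "BindingSiteHit",
    "read_pwm_transfac",
    "write_pwm_transfac",
    "match_scan",
    "count_sites",
    "background_density",
    "target_propensity",
    "build_propensity_table",
    "extract_promoter_windows",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N

DEFAULT_MSS_CUTOFF = 0.75
DEFAULT_CSS_CUTOFF = 0.90
CORE_LENGTH = 5


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, anything else=4)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(raw.size, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[raw == ord(base)] = code
    return out


@dataclass
class PWM:
    """A position count matrix plus the derived MATCH scoring machinery.

    Parameters
    ----------
    id : matrix accession/name.
    counts : (L, 4) array of base counts (columns ordered A, C, G, T).
    mss_cutoff, css_cutoff : minimum matrix / core similarity for a reported
        hit, both in [0, 1].  Defaults are permissive, mimicking a
        minimum-false-negative profile.
    pseudocount : added to every count cell before frequency normalisation so
        no frequency is zero.
    """

    id: str
    counts: np.ndarray
    mss_cutoff: float = DEFAULT_MSS_CUTOFF
    css_cutoff: float = DEFAULT_CSS_CUTOFF
    pseudocount: float = 1.0

    freqs: np.ndarray = field(init=False, repr=False)
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError(f"PWM {self.id!r}: counts must be (L, 4), got {c.shape}")
        if c.shape[0] < 1:
            raise ValueError(f"PWM {self.id!r}: empty matrix")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError(f"PWM {self.id!r}: counts must be finite and non-negative")
        self.counts = c
        smoothed = c + self.pseudocount
        self.freqs = smoothed / smoothed.sum(axis=1, keepdims=True)
        # information weight per position: I(i) = sum_b f(i,b) ln(4 f(i,b))
        self.info = np.sum(self.freqs * np.log(4.0 * self.freqs), axis=1)
        # core: the contiguous window (5 positions, or the whole matrix when
        # shorter) of maximal summed information
        self.core_length = min(CORE_LENGTH, c.shape[0])
        window_info = np.convolve(self.info, np.ones(self.core_length),
                                  mode="valid")
        self.core_start = int(np.argmax(window_info))  # first window on ties
        # scoring lookup: column 4 holds the per-position minimum frequency,
        # used for N (or otherwise unknown) bases
        lut = np.empty((self.length, 5))
        lut[:, :4] = self.info[:, None] * self.freqs
        lut[:, 4] = self.info * self.freqs.min(axis=1)
        self._lut = lut
        self._smin = lut[:, :4].min(axis=1)
        self._smax = lut[:, :4].max(axis=1)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def core_slice(self) -> slice:
        return slice(self.core_start, self.core_start + self.core_length)

    @property
    def consensus(self) -> str:
        """Argmax base per position (no degeneracy coding)."""
        return "".join(BASES[i] for i in np.argmax(self.freqs, axis=1))


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    promoter_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class PromoterSet:
    """An ordered collection of promoters, grouped by gene on demand."""

    def __init__(self, promoters: Iterable[Promoter]):
        self.promoters = list(promoters)
        ids = [p.promoter_id for p in self.promoters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate promoter IDs in promoter set")

    def __len__(self) -> int:
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    def by_gene(self) -> dict[str, list[Promoter]]:
        out: dict[str, list[Promoter]] = {}
        for p in self.promoters:
            out.setdefault(p.gene_id, []).append(p)
        return out

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.promoters:
            seen.setdefault(p.gene_id)
        return list(seen)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.promoters:
                fh.write(f">{p.gene_id}|{p.promoter_id}\n")
                for i in range(0, len(p.sequence), 80):
                    fh.write(p.sequence[i : i + 80] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "PromoterSet":
        from Bio import SeqIO

        promoters = []
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.id
            if "|" in header:
                gene_id, promoter_id = header.split("|", 1)
            else:
                gene_id = promoter_id = header
            promoters.append(Promoter(gene_id, promoter_id, str(rec.seq).upper()))
        return cls(promoters)


@dataclass(frozen=True)
class BindingSiteHit:
    promoter_id: str
    offset: int  # 0-based start on the forward strand
    strand: str  # "+" or "-"
    mss: float
    css: float


# ---------------------------------------------------------------------------
# TRANSFAC flat-format I/O (AC/ID, P0 header, numbered rows, // terminator)
# ---------------------------------------------------------------------------

def read_pwm_transfac(path, mss_cutoff: float = DEFAULT_MSS_CUTOFF,
                      css_cutoff: float = DEFAULT_CSS_CUTOFF,
                      pseudocount: float = 1.0) -> list[PWM]:
    """Parse a TRANSFAC flat file into PWMs (pseudo-count smoothing applied)."""
    with open(path) as fh:
        try:
            records = _bio_motifs.parse(fh, "TRANSFAC")
        except Exception as exc:  # malformed record
            raise ValueError(f"cannot parse TRANSFAC file {path}: {exc}") from exc
    pwms = []
    for rec in records:
        name = rec.get("ID") or rec.get("AC") or f"matrix_{len(pwms)}"
        counts = np.column_stack([np.asarray(rec.counts[b], float) for b in BASES])
        if counts.size == 0:
            raise ValueError(f"empty matrix {name!r} in {path}")
        pwms.append(PWM(id=name, counts=counts, mss_cutoff=mss_cutoff,
                        css_cutoff=css_cutoff, pseudocount=pseudocount))
    if not pwms:
        raise ValueError(f"no matrices found in {path}")
    return pwms


def write_pwm_transfac(pwms: Sequence[PWM], path) -> None:
    """Write PWMs (raw counts) to a TRANSFAC flat file."""
    records = []
    for pwm in pwms:
        counts = {b: list(pwm.counts[:, i]) for i, b in enumerate(BASES)}
        m = _transfac.Motif(alphabet="GATC", counts=counts)
        m["AC"] = pwm.id
        m["ID"] = pwm.id
        records.append(m)
    with open(path, "w") as fh:
        fh.write(_transfac.write(records))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """MSS and CSS for every offset of the encoded sequence (one strand)."""
    L = pwm.length
    n_off = codes.size - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    pos = np.arange(L)
    contrib = pwm._lut[pos[None, :], windows]  # (n_off, L)
    cur = contrib.sum(axis=1)
    smin, smax = pwm._smin.sum(), pwm._smax.sum()
    mss = (cur - smin) / (smax - smin) if smax > smin else np.ones(n_off)
    core = pwm.core_slice
    cur_c = contrib[:, core].sum(axis=1)
    cmin, cmax = pwm._smin[core].sum(), pwm._smax[core].sum()
    css = (cur_c - cmin) / (cmax - cmin) if cmax > cmin else np.ones(n_off)
    return mss, css


def match_scan(promoter: Promoter, pwm: PWM) -> list[BindingSiteHit]:
    """Scan both strands of a promoter; return hits passing both cutoffs.

    Offsets are 0-based starts on the forward strand regardless of the hit's
    strand.  N bases contribute the position's minimum frequency, degrading
    rather than invalidating the window score.
    """
    L = pwm.length
    codes = encode_sequence(promoter.sequence)
    if codes.size < L:
        return []
    hits: list[BindingSiteHit] = []
    mss, css = _window_scores(codes, pwm)
    rc = _COMPLEMENT_CODE[codes[::-1]]
    mss_rc, css_rc = _window_scores(rc, pwm)
    n = codes.size
    for off in np.nonzero((mss >= pwm.mss_cutoff) & (css >= pwm.css_cutoff))[0]:
        hits.append(BindingSiteHit(promoter.promoter_id, int(off), "+",
                                   float(mss[off]), float(css[off])))
    for off in np.nonzero((mss_rc >= pwm.mss_cutoff) & (css_rc >= pwm.css_cutoff))[0]:
        fwd_off = n - L - int(off)
        hits.append(BindingSiteHit(promoter.promoter_id, fwd_off, "-",
                                   float(mss_rc[off]), float(css_rc[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def hit_table(promoters: PromoterSet, pwm: PWM) -> pd.DataFrame:
    """Per-promoter table of all passing hits (offset, strand, MSS, CSS)."""
    rows = [
        {"promoter_id": h.promoter_id, "offset": h.offset, "strand": h.strand,
         "mss": h.mss, "css": h.css}
        for p in promoters for h in match_scan(p, pwm)
    ]
    return pd.DataFrame(rows, columns=["promoter_id", "offset", "strand",
                                       "mss", "css"])


def count_sites(promoters: PromoterSet, pwm: PWM) -> pd.Series:
    """Number of passing hits per promoter (both strands, overlaps all counted)."""
    counts = {p.promoter_id: len(match_scan(p, pwm)) for p in promoters}
    return pd.Series(counts, name="n_sites", dtype=int)


def background_density(promoters: PromoterSet, counts: Mapping[str, int]) -> float:
    """Global site density rho = total sites / total promoter bases."""
    total_len = sum(p.length for p in promoters)
    if total_len == 0:
        raise ValueError("background density undefined: zero total promoter length")
    total_sites = sum(int(counts[p.promoter_id]) for p in promoters)
    rho = total_sites / total_len
    if rho == 0:
        raise ValueError(
            "background density is zero (no sites anywhere); target propensity undefined"
        )
    return rho


def target_propensity(gene_promoters: Sequence[Promoter],
                      counts: Mapping[str, int], rho: float) -> float:
    """Mean over a gene's promoters of observed site density relative to rho."""
    if not gene_promoters:
        raise ValueError("gene has no promoters")
    if rho <= 0:
        raise ValueError("rho must be positive")
    acc = 0.0
    for p in gene_promoters:
        if p.length == 0:
            raise ValueError(f"promoter {p.promoter_id!r} has zero length")
        acc += counts[p.promoter_id] / (rho * p.length)
    return acc / len(gene_promoters)


def build_propensity_table(promoters: PromoterSet, pwm: PWM) -> pd.DataFrame:
    """Scan all promoters and assemble the per-gene target-propensity table.

    Returns a DataFrame indexed by gene with columns ``n_promoters``,
    ``n_sites`` (summed over promoters), ``tp`` and ``tp_rank`` (descending,
    rank 1 = highest propensity, ties broken by gene ID).  The global
    background density is attached as ``df.attrs["background_density"]``.
    """
    counts = count_sites(promoters, pwm)
    rho = background_density(promoters, counts)
    rows = []
    for gene, plist in promoters.by_gene().items():
        rows.append({
            "gene": gene,
            "n_promoters": len(plist),
            "n_sites": int(sum(counts[p.promoter_id] for p in plist)),
            "tp": target_propensity(plist, counts, rho),
        })
    df = pd.DataFrame(rows).set_index("gene")
    order = df.reset_index().sort_values(
        ["tp", "gene"], ascending=[False, True], kind="mergesort"
    )["gene"]
    df["tp_rank"] = pd.Series(np.arange(1, len(order) + 1), index=order).astype(int)
    df.attrs["background_density"] = rho
    df.attrs["pwm_id"] = pwm.id
    return df


# ---------------------------------------------------------------------------
# Promoter window extraction from a genome
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def extract_promoter_windows(bed_path, genome_fasta, upstream: int = 500,
                             downstream: int = 100) -> PromoterSet:
    """Cut promoter windows around annotated TSSs from a genome FASTA.

    ``bed_path`` is a BED6 file of TSS records (the TSS is the start
    coordinate for + strand records and end-1 for - strand records; all
    coordinates 0-based half-open).  The emitted window covers
    [TSS-upstream, TSS+downstream) in gene orientation and is
    reverse-complemented for - strand genes.  Windows running off a contig
    end are truncated with a logged warning.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    promoters = []
    seen: dict[str, int] = {}
    with open(bed_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{bed_path}:{line_no}: BED6 record expected")
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            if strand == "+":
                tss = start
                lo, hi = tss - upstream, tss + downstream
            elif strand == "-":
                tss = end - 1
                lo, hi = tss - downstream + 1, tss + upstream + 1
            else:
                raise ValueError(f"{bed_path}:{line_no}: strand must be + or -")
            contig_len = len(genome[chrom])
            clo, chi = max(lo, 0), min(hi, contig_len)
            if (clo, chi) != (lo, hi):
                logger.warning(
                    "promoter window for %s truncated to [%d, %d) on %s",
                    name, clo, chi, chrom,
                )
            seq = str(genome[chrom][clo:chi]).upper()
            if strand == "-":
                seq = seq.translate(_RC)[::-1]
            k = seen.get(name, 0)
            seen[name] = k + 1
            promoter_id = name if k == 0 else f"{name}.{k + 1}"
            promoters.append(Promoter(name, promoter_id, seq))
    return PromoterSet(promoters)
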