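"""SOLiD color-space encoding, quality statistics, and read simulation.

SOLiD reads are sequences of *colors*: each color encodes an overlapping
dimer of bases, so a read of ``m`` colors together with its primer base
determines ``m`` bases.  The dibase code used here is the standard
two-bit-XOR table (A=0, C=1, G=2, T=3; ``color = code(b1) ^ code(b2)``),
which has the defining properties of the SOLiD coding scheme:

* identical adjacent bases always map to color 0;
* a single base substitution changes exactly two adjacent colors
  (one color if the substitution hits the last base);
* ``n`` consecutive substitutions affect at most ``n + 1`` colors;
* a single color reading error corrupts the decoded sequence from that
  point onward, which is why mapping is done in color space.

The code table is pluggable in principle (any Latin-square dibase code
shares these properties), but the XOR table is the one used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "ColorRead",
    "QualityCorrelation",
    "encode_to_colors",
    "decode_from_colors",
    "quality_to_error_prob",
    "quality_correlation",
    "quality_correlation_profile",
    "simulate_reads",
    "read_csfasta",
    "write_csfasta",
    "read_qual",
    "write_qual",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class ColorRead:
    """A color-space read: primer base plus a sequence of colors 0-3."""

    colors: tuple[int, ...]
    primer_base: str
    qualities: tuple[int, ...] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        colors = tuple(int(c) for c in self.colors)
        object.__setattr__(self, "colors", colors)
        if any(c not in (0, 1, 2, 3) for c in colors):
            raise ValueError("colors must be in {0,1,2,3}")
        if self.primer_base not in _BASE_CODE:
            raise ValueError(f"primer base must be one of ACGT, got {self.primer_base!r}")
        if self.qualities is not None:
            quals = tuple(int(q) for q in self.qualities)
            object.__setattr__(self, "qualities", quals)
            if len(quals) != len(colors):
                raise ValueError(
                    f"{len(quals)} qualities for {len(colors)} colors"
                )
            if any(q < 0 for q in quals):
                raise ValueError("qualities must be non-negative")

    def __len__(self) -> int:
        return len(self.colors)


def encode_to_colors(bases: str, primer_base: str) -> ColorRead:
    """Encode a nucleotide string into a color read.

    Color ``l`` is the dimer code of (previous base, current base); the
    first dimer pairs the primer base with the first base.
    """
    if not bases:
        raise ValueError("cannot encode an empty sequence")
    if primer_base.upper() not in _BASE_CODE:
        raise ValueError(f"primer base must be one of ACGT, got {primer_base!r}")
    seq = bases.upper()
    for i, ch in enumerate(seq):
        if ch not in _BASE_CODE:
            raise ValueError(f"invalid base {bases[i]!r} at position {i}")
    prev = _BASE_CODE[primer_base.upper()]
    colors = []
    for ch in seq:
        cur = _BASE_CODE[ch]
        colors.append(prev ^ cur)
        prev = cur
    return ColorRead(tuple(colors), primer_base.upper())


def decode_from_colors(read: ColorRead) -> str:
    """Invert :func:`encode_to_colors`.  Total on valid reads; the empty
    color list decodes to the empty string."""
    code = _BASE_CODE[read.primer_base]
    out = []
    for c in read.colors:
        code ^= c
        out.append(_BASES[code])
    return "".join(out)


def quality_to_error_prob(quality: int) -> float:
    """Phred-style conversion ``p = 10^(-Q/10)``."""
    if quality < 0:
        raise ValueError(f"quality must be non-negative, got {quality}")
    return 10.0 ** (-quality / 10.0)


@dataclass(frozen=True)
class QualityCorrelation:
    """Quality autocorrelation by positional lag, pooled over reads."""

    lags: tuple[int, ...]
    c: tuple[float, ...]
    mean_quality: float
    std_quality: float


def _quality_matrix(reads) -> np.ndarray:
    if isinstance(reads, np.ndarray):
        mat = np.asarray(reads, dtype=float)
        if mat.ndim != 2:
            raise ValueError("quality array must be 2-D (reads x positions)")
        return mat
    rows = []
    m = None
    for r in reads:
        if r.qualities is None:
            raise ValueError("all reads must carry qualities")
        if m is None:
            m = len(r.qualities)
        elif len(r.qualities) != m:
            raise ValueError("all reads must have the same length")
        rows.append(r.qualities)
    if not rows:
        raise ValueError("no reads given")
    return np.asarray(rows, dtype=float)


def quality_correlation(reads, lag: int) -> float:
    """Empirical quality correlation ``c(i)`` at a single lag.

    ``c(i) = E((Q_j - mean)(Q_{j+i} - mean)) / var``, where mean and
    variance are pooled over all positions of all reads and the
    expectation averages over all reads and all valid positions ``j``.
    The raw statistic is returned (no clamping).
    """
    mat = _quality_matrix(reads)
    m = mat.shape[1]
    if not 1 <= lag <= m - 1:
        raise ValueError(f"lag must be in 1..{m - 1}, got {lag}")
    mean = mat.mean()
    var = mat.var()
    if var == 0:
        raise ValueError("quality correlation undefined for constant qualities")
    centered = mat - mean
    return float(np.mean(centered[:, :-lag] * centered[:, lag:]) / var)


def quality_correlation_profile(reads) -> QualityCorrelation:
    """``c(i)`` for every lag ``1..m-1``."""
    mat = _quality_matrix(reads)
    m = mat.shape[1]
    mean = mat.mean()
    var = mat.var()
    if var == 0:
        raise ValueError("quality correlation undefined for constant qualities")
    centered = mat - mean
    lags = tuple(range(1, m))
    c = tuple(
        float(np.mean(centered[:, :-i] * centered[:, i:]) / var) for i in lags
    )
    return QualityCorrelation(lags, c, float(mean), float(np.sqrt(var)))


def baseline_error_profile(m: int, start: float, end: float) -> np.ndarray:
    """Per-position baseline reading-error probability: linear ramp from
    ``start`` at the first color to ``end`` at the last one."""
    if m == 1:
        return np.array([start])
    return start + (end - start) * np.arange(m) / (m - 1)


def simulate_reads(
    reference: str,
    n_reads: int,
    m: int,
    params: ModelParams | None = None,
    rng_seed: int | None = None,
    primer_base: str = "T",
) -> list[tuple[int, ColorRead]]:
    """Simulate SOLiD color reads from a reference sequence.

    Each read is sampled from a uniformly random forward-strand locus and
    carries the statistical structure of real color reads:

    * SNPs (probability ``p_snp`` per base) change two adjacent colors;
    * color indels (probability ``p_indel`` per color) are preceded by a
      color mismatch in 3/4 of cases;
    * reading errors occur with a per-position probability that is the
      maximum of a rising baseline (``p_err_start`` .. ``p_err_end``) and
      a periodic component: error-prone period-5 phases accumulate along
      the read (switching probability ``p_switch``) and marked phases err
      with probability ``p_err_periodic``;
    * qualities track the realized per-position error probability and
      carry an injected lag-5 correlated component of strength
      ``quality_lag5_rho``.

    Returns a list of ``(true 0-based locus, ColorRead)`` pairs;
    deterministic given ``rng_seed``.
    """
    if rng_seed is None:
        raise ValueError("rng_seed is required for reproducible simulation")
    params = params or ModelParams()
    ref = reference.upper()
    for i, ch in enumerate(ref):
        if ch not in _BASE_CODE:
            raise ValueError(f"invalid base {reference[i]!r} at position {i}")
    if len(ref) < m + 1:
        raise ValueError(
            f"reference of length {len(ref)} too short for reads of {m} colors "
            f"(needs at least {m + 1} bases)"
        )
    rng = np.random.default_rng(rng_seed)
    ref_codes = np.array([_BASE_CODE[ch] for ch in ref], dtype=np.int64)
    primer_code = _BASE_CODE[primer_base.upper()]
    extra = 8  # spare template colors to absorb deletions
    baseline = baseline_error_profile(m, params.p_err_start, params.p_err_end)
    positions = np.arange(m)
    phases = positions % 5
    # quality noise: total extra variance 9, split so that the lag-5
    # component alone yields correlation quality_lag5_rho
    q_var = 9.0
    amp = float(np.sqrt(params.quality_lag5_rho * q_var))
    sig = float(np.sqrt((1.0 - params.quality_lag5_rho) * q_var))

    out: list[tuple[int, ColorRead]] = []
    max_start = len(ref) - (m + 1)
    for _ in range(n_reads):
        locus = int(rng.integers(0, max_start + 1))
        frag = ref_codes[locus : locus + m + 1 + extra].copy()
        # SNPs at the base level
        snp_mask = rng.random(frag.shape[0]) < params.p_snp
        n_snp = int(snp_mask.sum())
        if n_snp:
            frag[snp_mask] = (frag[snp_mask] + 1 + rng.integers(0, 3, n_snp)) % 4
        # encode to colors (primer pairs with the first fragment base)
        full = np.concatenate(([primer_code], frag))
        colors = (full[1:] ^ full[:-1]).tolist()
        # color indels, optionally preceded by a color mismatch
        indel_mask = rng.random(len(colors)) < params.p_indel
        if indel_mask.any():
            edited: list[int] = []
            for j, c in enumerate(colors):
                if indel_mask[j]:
                    if edited and rng.random() < params.p_indel_pre_mismatch:
                        edited[-1] = (edited[-1] + 1 + int(rng.integers(0, 3))) % 4
                    if rng.random() < 0.5:
                        continue  # deletion of this color
                    edited.append(int(rng.integers(0, 4)))  # insertion
                edited.append(c)
            colors = edited
        if len(colors) < m:  # deletions ate the spare template: pad randomly
            colors = colors + rng.integers(0, 4, m - len(colors)).tolist()
        colors = colors[:m]
        # reading errors: rising baseline plus accumulating period-5 phases
        switches = rng.random(m) < params.p_switch
        marked = np.zeros(m, dtype=bool)
        for phi in range(5):
            sel = phases == phi
            if sel.any():
                marked[sel] = np.maximum.accumulate(switches[sel])
        p_err = np.maximum(baseline, np.where(marked, params.p_err_periodic, 0.0))
        err_mask = rng.random(m) < p_err
        if err_mask.any():
            arr = np.asarray(colors)
            arr[err_mask] = (
                arr[err_mask] + 1 + rng.integers(0, 3, int(err_mask.sum()))
            ) % 4
            colors = arr.tolist()
        # qualities: Phred trend of the realized error probability plus an
        # injected per-read lag-5 component and white noise
        z = rng.standard_normal(5)
        q = (
            -10.0 * np.log10(np.maximum(p_err, 1e-4))  # floor at Q = 40
            + amp * z[phases]
            + sig * rng.standard_normal(m)
        )
        quals = np.clip(np.rint(q), 0, 60).astype(int)
        out.append(
            (locus, ColorRead(tuple(colors), primer_base.upper(), tuple(quals)))
        )
    return out


# ---------------------------------------------------------------------------
# csfasta / QUAL input-output
# ---------------------------------------------------------------------------

def read_csfasta(path) -> list[ColorRead]:
    """Read color-space FASTA: ``>`` headers, records of a primer base
    followed by color digits.  ``#`` lines are comments."""
    reads: list[ColorRead] = []
    name = None
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        body = "".join(chunks)
        if not body:
            raise ValueError(f"record {name!r} has no sequence")
        primer, digits = body[0], body[1:]
        if primer.upper() not in _BASE_CODE:
            raise ValueError(f"record {name!r}: bad primer base {primer!r}")
        if any(d not in "0123" for d in digits):
            raise ValueError(f"record {name!r}: bad color characters")
        reads.append(
            ColorRead(tuple(int(d) for d in digits), primer.upper(), None, name)
        )

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence data before first header")
                chunks.append(line)
    flush()
    return reads


def write_csfasta(path, reads: Iterable[ColorRead], comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for i, r in enumerate(reads):
            name = r.name or f"read_{i}"
            fh.write(f">{name}\n{r.primer_base}{''.join(str(c) for c in r.colors)}\n")


def read_qual(path) -> dict[str, list[int]]:
    """Read a QUAL file (space-separated integers per record) via Biopython."""
    from Bio import SeqIO

    return {
        rec.id: list(rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(path, "qual")
    }


def write_qual(path, reads: Iterable[ColorRead]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, r in enumerate(reads):
        if r.qualities is None:
            raise ValueError("cannot write QUAL for reads without qualities")
        name = r.name or f"read_{i}"
        rec = SeqRecord(Seq("N" * len(r.colors)), id=name, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    seqio_write(records, path, "qual")


def attach_qualities(reads: Sequence[ColorRead], quals: dict[str, list[int]]) -> list[ColorRead]:
    """Pair csfasta reads with their QUAL records by name."""
    out = []
    for r in reads:
        if r.name not in quals:
            raise ValueError(f"no qualities for read {r.name!r}")
        out.append(ColorRead(r.colors, r.primer_base, tuple(quals[r.name]), r.name))
    return out
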