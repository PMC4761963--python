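"""Position weight matrices and MATCH-style information vectors.

A PWM is a width x 4 matrix of per-position base frequencies (columns in
A, C, G, T order). The information vector weights each position by how far
its base distribution departs from the uniform background,

    I(i) = sum_b f(i, b) * ln(4 * f(i, b)),    with 0 * ln 0 := 0,

so a uniform position contributes 0 and an invariant one ln 4. The "core"
of a matrix is the run of five consecutive positions with the largest
summed information; core similarity scores are computed on it alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.intp)  # A<->T, C<->G
CORE_WIDTH = 5

__all__ = [
    "PWM",
    "BASES",
    "CORE_WIDTH",
    "information_vector",
    "read_pwms",
    "read_transfac",
    "read_jaspar",
    "write_transfac",
]


def information_vector(freq: np.ndarray) -> np.ndarray:
    """Per-position information weights I(i) = sum_b f(i,b) ln(4 f(i,b)).

    ``freq`` must be a (width, 4) array of nonnegative rows each summing
    to 1. Zero frequencies contribute 0 by the 0*ln0 convention.
    """
    freq = np.asarray(freq, dtype=float)
    if freq.ndim != 2 or freq.shape[1] != 4:
        raise ValueError("frequency matrix must have shape (width, 4)")
    if (freq < 0).any():
        raise ValueError("frequencies must be nonnegative")
    if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each frequency row must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log(4.0 * freq), 0.0)
    info = terms.sum(axis=1)
    # tiny negative values can arise from rounding of near-uniform rows
    return np.maximum(info, 0.0)


@dataclass(frozen=True)
class PWM:
    """A base-frequency motif model with derived MATCH quantities."""

    id: str
    freq: np.ndarray
    tf_names: tuple[str, ...] = ()
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape[0] < CORE_WIDTH:
            raise ValueError(
                f"PWM {self.id!r}: width {freq.shape[0]} < {CORE_WIDTH}; "
                f"a {CORE_WIDTH}-position core must exist"
            )
        freq = freq / freq.sum(axis=1, keepdims=True)
        freq.setflags(write=False)
        object.__setattr__(self, "freq", freq)
        info = information_vector(freq)
        info.setflags(write=False)
        object.__setattr__(self, "info", info)
        sums = np.convolve(info, np.ones(CORE_WIDTH), mode="valid")
        object.__setattr__(self, "core_start", int(np.argmax(sums)))

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    def consensus(self) -> str:
        """Per-position argmax base (ties -> alphabetically first)."""
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    def reverse_complement_freq(self) -> np.ndarray:
        return self.freq[::-1, COMPLEMENT_INDEX]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return (
            self.id == other.id
            and self.tf_names == other.tf_names
            and np.array_equal(self.freq, other.freq)
        )

    def __hash__(self) -> int:
        return hash((self.id, self.tf_names, self.freq.tobytes()))


def _counts_to_freq(counts: np.ndarray, pseudocount: float = 0.01) -> np.ndarray:
    counts = np.asarray(counts, dtype=float) + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def read_transfac(text: str, pseudocount: float = 0.01) -> list[PWM]:
    """Parse a TRANSFAC-dialect flat file (DE / P0 / 01..NN / XX / //).

    Count rows are converted to frequencies after adding ``pseudocount``
    to every cell. The DE line supplies the matrix id; BF (or extra DE
    tokens) supply associated transcription-factor names.
    """
    pwms: list[PWM] = []
    cur_id: str | None = None
    tf_names: list[str] = []
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal cur_id, tf_names, rows
        if cur_id is not None and rows:
            pwms.append(
                PWM(cur_id, _counts_to_freq(np.array(rows), pseudocount), tuple(tf_names))
            )
        cur_id, tf_names, rows = None, [], []

    for line in text.splitlines():
        line = line.strip()
        if not line or line == "XX":
            continue
        if line == "//":
            flush()
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag in ("DE", "ID", "NA") and cur_id is None:
            parts = rest.split()
            cur_id = parts[0]
            tf_names.extend(parts[1:])
        elif tag == "BF":
            tf_names.append(rest.split(";")[0].strip())
        elif tag in ("P0", "PO"):
            continue
        elif re.fullmatch(r"\d+", tag):
            vals = rest.split()
            rows.append([float(v) for v in vals[:4]])
    flush()
    return pwms


def read_jaspar(text: str, pseudocount: float = 0.01) -> list[PWM]:
    """Parse JASPAR-format matrices: a '>' header then four base rows.

    Accepts both bracketed (``A [ 1 2 3 ]``) and bare 4-line layouts.
    """
    pwms: list[PWM] = []
    blocks = re.split(r"(?m)^>", text)
    for block in blocks:
        block = block.strip()
        if not block:
            continue
        lines = block.splitlines()
        header = lines[0].split()
        pwm_id = header[0]
        tf_names = tuple(header[1:])
        per_base: dict[str, list[float]] = {}
        for line in lines[1:]:
            m = re.match(r"\s*([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$", line)
            if m:
                per_base[m.group(1)] = [float(v) for v in m.group(2).split()]
        if len(per_base) != 4:
            raise ValueError(f"JASPAR record {pwm_id!r}: expected 4 base rows")
        counts = np.array([per_base[b] for b in BASES]).T
        pwms.append(PWM(pwm_id, _counts_to_freq(counts, pseudocount), tf_names))
    return pwms


def read_pwms(path: str, fmt: str = "auto", pseudocount: float = 0.01) -> list[PWM]:
    """Read PWMs from ``path``; ``fmt`` in {auto, transfac, jaspar}."""
    with open(path) as fh:
        text = fh.read()
    if fmt == "auto":
        fmt = "jaspar" if text.lstrip().startswith(">") else "transfac"
    if fmt == "transfac":
        return read_transfac(text, pseudocount)
    if fmt == "jaspar":
        return read_jaspar(text, pseudocount)
    raise ValueError(f"unknown PWM format {fmt!r}")


def write_transfac(pwms: list[PWM], path: str, scale: int = 100) -> None:
    """Write PWMs as a TRANSFAC-dialect flat file (frequencies x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            names = " ".join(pwm.tf_names)
            fh.write(f"DE {pwm.id} {names}".rstrip() + "\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.freq, start=1):
                vals = "  ".join(f"{v * scale:8.3f}" for v in row)
                fh.write(f"{i:02d}  {vals}\n")
            fh.write("XX\n//\n")
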