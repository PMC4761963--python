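"""MATCH-style promoter scanning and TFBS feature-matrix construction.

A window of PWM width w scores

    Current = sum_i I(i) * f(i, b_i)

and the matrix similarity score normalizes it to [0, 1],

    MSS = (Current - Min) / (Max - Min),

where Max (Min) replaces f(i, b_i) with the row maximum (minimum). The
core similarity score (CSS) is the same quantity restricted to the five
most informative consecutive positions. Both strands are scanned; minus
strand hits score the reverse complement but are reported in plus-strand
0-based half-open coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .pwm import BASE_INDEX, CORE_WIDTH, PWM

logger = logging.getLogger(__name__)

__all__ = ["MotifHit", "FeatureMatrix", "match_score", "scan", "scan_all",
           "build_features", "write_bed", "encode_sequence"]

_ENCODE = np.full(256, 4, dtype=np.intp)  # anything unexpected scores like N
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a base string to integer codes A,C,G,T -> 0..3; N/other -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM occurrence on a promoter (plus-strand coordinates)."""

    gene_id: str
    pwm_id: str
    position: int  # 0-based start of the half-open window
    strand: str  # '+' or '-'
    mss: float
    css: float


@dataclass
class FeatureMatrix:
    """Gene x TFBS hit-count features with an optional response vector.

    ``values`` is indexed by gene id with one integer column per TFBS id;
    ``response`` (when present) aligns with the same gene index and holds
    the per-gene mean log2 expression being modelled.
    """

    values: pd.DataFrame
    response: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in feature matrix: {dupes}")
        if self.response is not None:
            self.response = self.response.reindex(self.values.index)
            if self.response.isna().any():
                missing = self.response.index[self.response.isna()].tolist()
                raise ValueError(f"response missing for genes: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tfbs_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Iterable[str]) -> "FeatureMatrix":
        genes = [g for g in self.values.index if g in set(genes)]
        resp = self.response.loc[genes] if self.response is not None else None
        return FeatureMatrix(self.values.loc[genes], resp)

    def with_response(self, response: pd.Series) -> "FeatureMatrix":
        return FeatureMatrix(self.values, response)

    def to_tsv(self, path: str) -> None:
        out = self.values.copy()
        if self.response is not None:
            out.insert(0, "__response__", self.response)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        resp = None
        if "__response__" in df.columns:
            resp = df.pop("__response__")
        return cls(df, resp)


def _snap(x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Clip scores to [0, 1], snapping float-rounding residue at the ends.

    A consensus window must score exactly 1 (and an anticonsensus 0) so
    that cutoff-1.0 scans recover planted consensus sites.
    """
    x = np.clip(x, 0.0, 1.0)
    x = np.where(np.abs(x - 1.0) < tol, 1.0, x)
    return np.where(np.abs(x) < tol, 0.0, x)


def _score_components(pwm: PWM, reverse: bool = False):
    """Weighted score table S[i, b] = I(i) * f(i, b), N column = row min.

    With ``reverse`` the table scores the reverse-complement motif on the
    forward sequence, which is equivalent to scoring the minus strand.
    """
    freq = pwm.reverse_complement_freq() if reverse else pwm.freq
    info = pwm.info[::-1] if reverse else pwm.info
    s = info[:, None] * freq
    s = np.column_stack([s, s.min(axis=1)])  # code 4 (N) -> row minimum
    return s


def _bounds(pwm: PWM):
    s = pwm.info[:, None] * pwm.freq
    smax, smin = s.max(axis=1), s.min(axis=1)
    core = slice(pwm.core_start, pwm.core_start + CORE_WIDTH)
    return (
        smin.sum(), smax.sum(),
        smin[core].sum(), smax[core].sum(),
    )


def match_score(pwm: PWM, window: str) -> tuple[float, float]:
    """Matrix and core similarity scores of one window against ``pwm``.

    'N' bases contribute the row minimum, so ambiguity can never create a
    hit. A fully uninformative matrix (Max == Min) scores 0 with a warning.
    """
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    codes = encode_sequence(window)
    if (codes > 4).any():
        raise ValueError(f"invalid bases in window {window!r}")
    s = _score_components(pwm)
    current = s[np.arange(pwm.width), codes]
    mn, mx, core_mn, core_mx = _bounds(pwm)
    core = slice(pwm.core_start, pwm.core_start + CORE_WIDTH)

    def _norm(cur: float, lo: float, hi: float) -> float:
        if hi - lo <= 0.0:
            logger.warning("PWM %s: uninformative matrix, score defined as 0", pwm.id)
            return 0.0
        return float(_snap(np.asarray((cur - lo) / (hi - lo))))

    mss = _norm(current.sum(), mn, mx)
    css = _norm(current[core].sum(), core_mn, core_mx)
    return mss, css


def _window_scores(pwm: PWM, codes: np.ndarray, reverse: bool):
    """MSS and CSS for every width-window of an encoded sequence."""
    w = pwm.width
    windows = sliding_window_view(codes, w)  # (n_windows, w)
    s = _score_components(pwm, reverse=reverse)
    contrib = s[np.arange(w)[None, :], windows]  # (n_windows, w)
    mn, mx, core_mn, core_mx = _bounds(pwm)
    if reverse:
        # core positions of the motif map to mirrored window positions
        core_lo = w - (pwm.core_start + CORE_WIDTH)
    else:
        core_lo = pwm.core_start
    core = slice(core_lo, core_lo + CORE_WIDTH)
    cur = contrib.sum(axis=1)
    cur_core = contrib[:, core].sum(axis=1)
    if mx - mn <= 0.0:
        logger.warning("PWM %s: uninformative matrix, score defined as 0", pwm.id)
        return np.zeros_like(cur), np.zeros_like(cur)
    mss = _snap((cur - mn) / (mx - mn))
    css = (
        _snap((cur_core - core_mn) / (core_mx - core_mn))
        if core_mx > core_mn
        else np.zeros_like(cur)
    )
    return mss, css


def scan(
    pwm: PWM,
    promoter: str,
    mss_cutoff: float = 0.85,
    css_cutoff: float = 0.90,
    gene_id: str = "",
) -> list[MotifHit]:
    """Score every window of ``promoter`` on both strands against ``pwm``.

    Returns hits with mss >= mss_cutoff and css >= css_cutoff, sorted by
    position then strand ('+' first). Promoters shorter than the motif
    yield an empty list.
    """
    for name, c in (("mss_cutoff", mss_cutoff), ("css_cutoff", css_cutoff)):
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {c}")
    if len(promoter) < pwm.width:
        return []
    codes = encode_sequence(promoter)
    hits: list[MotifHit] = []
    for strand, reverse in (("+", False), ("-", True)):
        mss, css = _window_scores(pwm, codes, reverse)
        keep = np.flatnonzero((mss >= mss_cutoff) & (css >= css_cutoff))
        for pos in keep:
            hits.append(
                MotifHit(gene_id, pwm.id, int(pos), strand,
                         float(mss[pos]), float(css[pos]))
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_all(
    pwms: Sequence[PWM],
    promoters: Mapping[str, str],
    mss_cutoff: float = 0.85,
    css_cutoff: float = 0.90,
) -> list[MotifHit]:
    """Scan every promoter with every PWM; hits ordered by gene then PWM."""
    hits: list[MotifHit] = []
    for gene_id, seq in promoters.items():
        for pwm in pwms:
            hits.extend(scan(pwm, seq, mss_cutoff, css_cutoff, gene_id=gene_id))
    return hits


def build_features(
    hits: Iterable[MotifHit],
    genes: Sequence[str],
    tfbs_ids: Sequence[str],
) -> FeatureMatrix:
    """Count hits per (gene, PWM) into a feature matrix.

    Genes with no hits (e.g. no promoter sequence) get an all-zero row;
    a warning names them. Duplicate gene ids are rejected.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    values = pd.DataFrame(
        np.zeros((len(genes), len(tfbs_ids)), dtype=int),
        index=pd.Index(genes, name="gene_id"),
        columns=list(tfbs_ids),
    )
    seen = set()
    for hit in hits:
        if hit.gene_id not in values.index:
            raise ValueError(f"hit for unknown gene {hit.gene_id!r}")
        values.loc[hit.gene_id, hit.pwm_id] += 1
        seen.add(hit.gene_id)
    silent = [g for g in genes if g not in seen]
    if silent:
        logger.warning("%d gene(s) have no motif hits: %s ...", len(silent), silent[:5])
    return FeatureMatrix(values)


def write_bed(
    hits: Iterable[MotifHit], pwms: Sequence[PWM], path: str
) -> None:
    """Write hits as BED6: gene, start, end, pwm id, round(1000*mss), strand."""
    pwm_widths = {p.id: p.width for p in pwms}
    with open(path, "w") as fh:
        for h in hits:
            end = h.position + pwm_widths[h.pwm_id]
            fh.write(
                f"{h.gene_id}\t{h.position}\t{end}\t{h.pwm_id}\t"
                f"{round(1000 * h.mss)}\t{h.strand}\n"
            )
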