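"""Alignment-cluster filtering ahead of expression quantification.

Orthogroup alignments go through: (1) trimming of terminal columns that
contain any gap, so every retained terminal column is sampled in all taxa;
(2) a >=300 bp aligned-length filter; (3) per-sequence degapping with
exclusion of sequences shorter than 300 bp once ungapped; (4) realignment
through a pluggable external hook; (5) removal of every remaining gapped
column, with the length check re-applied. Clusters that fall below two
sequences or the length floor at any stage are dropped, and every
cluster's fate is logged.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd

from . import io as cio

GAP = "-"
DEFAULT_MIN_LEN = 300


@dataclass(frozen=True)
class AlignmentCluster:
    cluster_id: str
    sequences: tuple[tuple[str, str], ...]  # (label, sequence), order preserved

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError(f"{self.cluster_id}: cluster needs >=2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"{self.cluster_id}: unequal sequence lengths {sorted(lengths)}")

    @property
    def aligned_length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.sequences)

    @classmethod
    def from_mapping(cls, cluster_id: str, seqs: Mapping[str, str]) -> "AlignmentCluster":
        return cls(cluster_id, tuple(seqs.items()))

    def to_mapping(self) -> dict[str, str]:
        return dict(self.sequences)


class ClusterDropped(ValueError):
    """A filtering stage removed the whole cluster."""


def _keep_columns(cluster: AlignmentCluster, keep: list[int]) -> AlignmentCluster:
    seqs = tuple((lab, "".join(s[i] for i in keep)) for lab, s in cluster.sequences)
    if not keep:
        raise ClusterDropped(f"{cluster.cluster_id}: no columns left")
    return replace(cluster, sequences=seqs)


def strip_terminal_gap_columns(cluster: AlignmentCluster,
                               mode: str = "anygap") -> AlignmentCluster:
    """Trim leading/trailing columns containing gaps; interior columns stay.

    ``anygap`` (default) trims terminal columns with at least one gap, so
    trimming stops at the first/last fully-ungapped column. ``allgap``
    trims only terminal columns that are gap in every sequence.
    """
    if mode not in ("anygap", "allgap"):
        raise ValueError(f"unknown trim mode {mode!r}")
    cols = list(zip(*(s for _, s in cluster.sequences)))
    if mode == "anygap":
        bad = [GAP in c for c in cols]
    else:
        bad = [all(ch == GAP for ch in c) for c in cols]
    first = next((i for i, b in enumerate(bad) if not b), None)
    if first is None:
        raise ClusterDropped(f"{cluster.cluster_id}: trimming removed every column")
    last = len(cols) - 1 - next(i for i, b in enumerate(reversed(bad)) if not b)
    return _keep_columns(cluster, list(range(first, last + 1)))


def filter_by_aligned_length(clusters, min_len: int = DEFAULT_MIN_LEN):
    """Keep clusters whose aligned length is >= min_len (inclusive)."""
    kept, dropped = [], []
    for c in clusters:
        (kept if c.aligned_length >= min_len else dropped).append(c)
    return kept, dropped


def degap_and_drop_short(cluster: AlignmentCluster,
                         min_len: int = DEFAULT_MIN_LEN) -> dict[str, str]:
    """Remove all gaps per sequence; exclude ungapped sequences < min_len.

    Returns the surviving unaligned sequences; fewer than two survivors
    drops the cluster.
    """
    out = {}
    for lab, s in cluster.sequences:
        ungapped = s.replace(GAP, "")
        if len(ungapped) >= min_len:
            out[lab] = ungapped
    if len(out) < 2:
        raise ClusterDropped(
            f"{cluster.cluster_id}: fewer than 2 sequences >= {min_len} bp after degapping"
        )
    return out


def drop_gap_columns(cluster: AlignmentCluster) -> AlignmentCluster:
    """Remove every column that contains at least one gap."""
    cols = list(zip(*(s for _, s in cluster.sequences)))
    keep = [i for i, c in enumerate(cols) if GAP not in c]
    if not keep:
        raise ClusterDropped(f"{cluster.cluster_id}: no gapless columns")
    return _keep_columns(cluster, keep)


Realigner = Callable[[dict[str, str]], dict[str, str]]


def identity_realigner(seqs: dict[str, str]) -> dict[str, str]:
    """Pad unaligned sequences with trailing gaps to a common length.

    Stands in for an external aligner on synthetic fixtures whose
    sequences are already co-linear; equal-length inputs pass unchanged.
    """
    width = max(len(s) for s in seqs.values())
    return {lab: s + GAP * (width - len(s)) for lab, s in seqs.items()}


def command_realigner(template: str) -> Realigner:
    """Wrap an external alignment command, e.g. ``mafft {in} > {out}``.

    The template receives ``{in}`` and ``{out}`` FASTA paths; the command
    must write an aligned FASTA to ``{out}`` (or stdout if redirected).
    """

    def run(seqs: dict[str, str]) -> dict[str, str]:
        with tempfile.TemporaryDirectory() as tmp:
            fin = Path(tmp) / "in.fasta"
            fout = Path(tmp) / "out.fasta"
            cio.write_alignment_fasta(seqs, fin)
            cmd = template.replace("{in}", str(fin)).replace("{out}", str(fout))
            subprocess.run(cmd, shell=True, check=True, capture_output=True)
            return cio.read_alignment_fasta(fout)

    return run


def run_filter_pipeline(clusters, min_len: int = DEFAULT_MIN_LEN,
                        realigner: Realigner = identity_realigner,
                        trim_mode: str = "anygap",
                        recheck_length: bool = True):
    """Full filter: trim -> length filter -> degap/drop-short -> realign ->
    drop gap columns (-> length re-check).

    Returns (final clusters, fate report DataFrame). A realigner failure
    marks the cluster "failed_realign" and the pipeline continues.
    """
    final = []
    fates = []
    for c in clusters:
        n_in, len_in = len(c.sequences), c.aligned_length
        fate = "passed"
        n_out = len_out = 0
        try:
            try:
                trimmed = strip_terminal_gap_columns(c, mode=trim_mode)
            except ClusterDropped:
                raise ClusterDropped("dropped_trim")
            if trimmed.aligned_length < min_len:
                raise ClusterDropped("dropped_length")
            try:
                degapped = degap_and_drop_short(trimmed, min_len=min_len)
            except ClusterDropped:
                raise ClusterDropped("dropped_short_seqs")
            try:
                realigned = realigner(degapped)
            except Exception:  # noqa: BLE001 - external hook, keep going
                raise ClusterDropped("failed_realign")
            cluster2 = AlignmentCluster.from_mapping(c.cluster_id, realigned)
            try:
                clean = drop_gap_columns(cluster2)
            except ClusterDropped:
                raise ClusterDropped("dropped_recheck")
            if recheck_length and clean.aligned_length < min_len:
                raise ClusterDropped("dropped_recheck")
            final.append(clean)
            n_out, len_out = len(clean.sequences), clean.aligned_length
        except ClusterDropped as exc:
            fate = str(exc)
        fates.append({
            "cluster": c.cluster_id, "stage_dropped": fate if fate != "passed" else "NA",
            "fate": fate, "n_seqs_in": n_in, "n_seqs_out": n_out,
            "len_in": len_in, "len_out": len_out,
        })
    return final, pd.DataFrame(fates)


def read_cluster_dir(path: str | Path) -> list[AlignmentCluster]:
    """Load every ``*.fasta``/``*.fa`` in a directory as one cluster each."""
    clusters = []
    for f in sorted(Path(path).glob("*.fa*")):
        clusters.append(AlignmentCluster.from_mapping(f.stem, cio.read_alignment_fasta(f)))
    if not clusters:
        raise FileNotFoundError(f"no FASTA clusters under {path}")
    return clusters


def write_cluster_dir(clusters, path: str | Path) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for c in clusters:
        cio.write_alignment_fasta(c.to_mapping(), out / f"{c.cluster_id}.fasta")
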