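"""Subprocess adapters for the homology search engines.

The pipeline can either ingest pre-computed tabular outputs or drive the
engines itself; these adapters run blastn (pairwise sequence mode) and
nhmmer (profile-HMM mode) and hand their tabular output to the parsers
in :mod:`mirscout.formats_io`.  cmsearch output is supported through the
pre-computed path.  All filter logic is engine-agnostic, so the cascade
is fully testable without any executable installed.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .formats_io import read_tabular_hits
from .homology import HomologyHit

DEFAULT_BLASTN_ARGS = [
    "-task", "blastn",
    "-word_size", "7",
    "-evalue", "10",
    "-dust", "no",
    "-soft_masking", "false",
]


def engine_available(executable: str) -> bool:
    return shutil.which(executable) is not None


def run_blastn(
    query_fasta: str | Path,
    genome_fasta: str | Path,
    query_lengths: dict[str, int] | None = None,
    extra_args: list[str] | None = None,
    executable: str = "blastn",
) -> list[HomologyHit]:
    """Run blastn of the family queries against the target genome and
    parse its outfmt-6 output (the -subject path needs no database)."""
    if not engine_available(executable):
        raise RuntimeError(
            f"{executable} not found on PATH; supply pre-computed hits instead"
        )
    with tempfile.NamedTemporaryFile(suffix=".tsv", mode="r") as out:
        cmd = [
            executable,
            "-query", str(query_fasta),
            "-subject", str(genome_fasta),
            "-outfmt", "6",
            "-out", out.name,
        ] + DEFAULT_BLASTN_ARGS + (extra_args or [])
        subprocess.run(cmd, check=True, capture_output=True, text=True)
        return read_tabular_hits(out.name, "blast-tab6", query_lengths)


def run_nhmmer(
    query_alignment: str | Path,
    genome_fasta: str | Path,
    query_lengths: dict[str, int] | None = None,
    extra_args: list[str] | None = None,
    executable: str = "nhmmer",
) -> list[HomologyHit]:
    """Run nhmmer with a (Stockholm) family alignment as query; the HMM
    is built on the fly.  Applies the engine's default inclusion
    threshold via --tblout parsing downstream."""
    if not engine_available(executable):
        raise RuntimeError(
            f"{executable} not found on PATH; supply pre-computed hits instead"
        )
    with tempfile.NamedTemporaryFile(suffix=".tblout", mode="r") as out:
        cmd = [
            executable,
            "--tblout", out.name,
            "--dna",
        ] + (extra_args or []) + [str(query_alignment), str(genome_fasta)]
        subprocess.run(cmd, check=True, capture_output=True, text=True)
        return read_tabular_hits(out.name, "nhmmer-tblout", query_lengths)
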