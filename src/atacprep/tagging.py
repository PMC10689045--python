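"""Move the cell barcode from aligned read names into the standard CB tag.

Demultiplexing prefixes each read name with its barcode (``BARCODE#name``);
after external alignment that prefix survives in the BAM query name.  Tagging
copies it into a ``CB:Z`` tag, which is where every downstream consumer
(fragment generation included) looks for the cell identity.  Reads whose name
carries no parseable prefix simply stay untagged.
"""

from __future__ import annotations

import re
import shlex
import shutil
import subprocess

import pysam

from .demux import DEFAULT_SEPARATOR

_BARCODE_RE = re.compile(r"^[ACGTN]+$")


def parse_barcode_prefix(name: str, separator: str = DEFAULT_SEPARATOR) -> str | None:
    """Return the barcode prefix of a read name, or None if there is none."""
    head, sep, _ = name.partition(separator)
    if not sep or not head or not _BARCODE_RE.match(head):
        return None
    return head


def tag_bam(bam_in, bam_out, separator: str = DEFAULT_SEPARATOR) -> dict[str, int]:
    """Write a copy of ``bam_in`` with CB:Z tags derived from read-name prefixes.

    Record order and count are preserved; read names keep their prefix, so the
    operation is idempotent.  Returns ``{"tagged": n, "untagged": m}``.
    """
    counts = {"tagged": 0, "untagged": 0}
    with pysam.AlignmentFile(str(bam_in), "rb") as src:
        with pysam.AlignmentFile(str(bam_out), "wb", template=src) as dst:
            for read in src:
                barcode = parse_barcode_prefix(read.query_name, separator)
                if barcode is not None:
                    read.set_tag("CB", barcode, value_type="Z")
                    counts["tagged"] += 1
                else:
                    counts["untagged"] += 1
                dst.write(read)
    return counts


def dedup_hook(bam_in, bam_out, external_cmd: str | None = None) -> dict:
    """Optional external duplicate-removal step (e.g. samtools markdup).

    With no command configured the BAM passes through unchanged — fragment
    collapsing downstream absorbs PCR duplicates anyway, and the log records
    that.  ``external_cmd`` may reference ``{input}`` and ``{output}``
    placeholders; without placeholders it runs as a shell filter
    (``cmd < input > output``).  A non-zero exit raises with the command's
    stderr attached.
    """
    if external_cmd is None:
        shutil.copyfile(str(bam_in), str(bam_out))
        return {
            "external_cmd": None,
            "note": "no external dedup configured; PCR duplicates are collapsed "
            "at the fragment level",
        }
    if "{input}" in external_cmd or "{output}" in external_cmd:
        cmd = external_cmd.format(input=str(bam_in), output=str(bam_out))
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    else:
        with open(bam_in, "rb") as fin, open(bam_out, "wb") as fout:
            proc = subprocess.run(
                shlex.split(external_cmd), stdin=fin, stdout=fout, stderr=subprocess.PIPE
            )
            proc = subprocess.CompletedProcess(
                proc.args, proc.returncode, stderr=proc.stderr.decode(errors="replace")
            )
    if proc.returncode != 0:
        raise RuntimeError(
            f"external dedup command failed (exit {proc.returncode}): {proc.stderr}"
        )
    return {"external_cmd": external_cmd}
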