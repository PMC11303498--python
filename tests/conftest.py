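from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from updscreen.genome import GenomeBuild
from updscreen.vcf_io import SITE_COLUMNS


@pytest.fixture
def toy_build():
    """Tiny genome: every 'autosome' is 1e6 bp for fast simulations."""
    return GenomeBuild(
        "toy", {str(i): 1_000_000 for i in range(1, 23)}
    )


def write_vcf_text(path: Path, records: list[str], sample: str = "S1") -> Path:
    """Write a minimal single-sample VCF from pre-formatted data lines.

    Each record is 'CHROM POS REF ALT GT AD' whitespace-separated; AD is the
    comma-joined allelic depths, ALT may be comma-joined for multi-allelics.
    """
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1,length=249000000>",
        "##contig=<ID=2,length=243000000>",
        "##contig=<ID=3,length=198000000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    lines = list(header)
    for rec in records:
        chrom, pos, ref, alt, gt, ad = rec.split()
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t{gt}:{ad}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def vcf_writer(tmp_path):
    def _write(records, name="sample.vcf", sample="S1"):
        return write_vcf_text(tmp_path / name, records, sample=sample)

    return _write


def site_frame(rows) -> pd.DataFrame:
    """rows of (chrom, pos, ref, alt, gt, depth, alt_fraction)."""
    frame = pd.DataFrame(rows, columns=SITE_COLUMNS)
    frame["pos"] = frame["pos"].astype(np.int64)
    frame["depth"] = frame["depth"].astype(np.int64)
    frame["alt_fraction"] = frame["alt_fraction"].astype(float)
    return frame
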