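#!/usr/bin/env python
"""Demonstrate the hard site filters on a small synthetic VCF whose INFO
annotations are constructed so that three of ten sites each violate exactly
one criterion (QD < 2, FS > 60, DP < 10).  Writes the filtered VCF and the
rejection report under results/02_filter/."""

import json
from pathlib import Path

from rilsweep.core import MarkerMap
from rilsweep.genotype_io import hard_filter_sites, read_vcf, write_vcf

OUT = Path("results/02_filter")

HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##INFO=<ID=QD,Number=1,Type=Float,Description="QD">\n'
    '##INFO=<ID=FS,Number=1,Type=Float,Description="FS">\n'
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">\n'
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum">\n'
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="RPRS">\n'
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
    "##contig=<ID=chr10,length=100000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tMM\tCC\n"
)
GOOD = "QD=25.0;FS=1.0;MQ=60.0;MQRankSum=0.5;ReadPosRankSum=0.3;DP=40"


def build_demo_vcf(path: Path) -> None:
    """Synthetic ten-site VCF: seven clean sites, three single-criterion
    violators."""
    lines = [f"chr10\t{1000 * (i + 1)}\tok{i}\tA\tG\t.\t.\t{GOOD}\tGT\t0/0\t1/1"
             for i in range(7)]
    lines.append("chr10\t8000\tbadQD\tA\tG\t.\t.\t"
                 + GOOD.replace("QD=25.0", "QD=1.5") + "\tGT\t0/0\t1/1")
    lines.append("chr10\t9000\tbadFS\tA\tG\t.\t.\t"
                 + GOOD.replace("FS=1.0", "FS=80.0") + "\tGT\t0/0\t1/1")
    lines.append("chr10\t10000\tbadDP\tA\tG\t.\t.\t"
                 + GOOD.replace("DP=40", "DP=5") + "\tGT\t0/0\t1/1")
    path.write_text(HEADER + "\n".join(lines) + "\n")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    vcf_in = OUT / "demo_sites.synthetic.vcf"
    build_demo_vcf(vcf_in)

    marker_map, G, records = read_vcf(vcf_in)
    kept, report = hard_filter_sites(records)
    kept_ids = [r.marker_id for r in kept]
    sub_map = MarkerMap(marker_map.table[marker_map.table["marker_id"].isin(kept_ids)])
    write_vcf(G.subset_markers(sub_map.marker_ids), sub_map,
              OUT / "filtered.vcf", records=kept)
    with open(OUT / "filter_report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    print(f"input sites: {report['n_input']}, kept: {report['n_kept']}, "
          f"removed: {report['n_removed']}")
    for crit in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP"):
        if report[crit]:
            print(f"  {crit}: {report[crit]} site(s) failed")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
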