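import pysam
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def bam_factory(tmp_path):
    """Build a small coordinate-sorted, indexed BAM from record dicts."""

    def make(records, contigs=None, name="test.bam"):
        contigs = contigs or {"chr21": 100_000}
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": c, "LN": l} for c, l in contigs.items()],
            }
        )
        names = list(contigs)
        segs = []
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r["name"]
            a.flag = r.get("flag", 0)
            a.reference_id = names.index(r.get("chrom", names[0]))
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            a.query_sequence = r.get("seq", "A" * a.infer_query_length())
            if "tags" in r:
                a.set_tags(r["tags"])
            segs.append(a)
        segs.sort(key=lambda a: (a.reference_id, a.reference_start))
        path = str(tmp_path / name)
        with pysam.AlignmentFile(path, "wb", header=header) as fh:
            for a in segs:
                fh.write(a)
        pysam.index(path)
        return path

    return make
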