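import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_gtf(tmp_path):
    """12 feature lines, 2 of them non-exon -> 10 exon records, 3 genes."""
    lines = [
        'chr1\tens\tgene\t1\t5000\t.\t+\t.\tgene_id "gA";',
        'chr1\tens\texon\t101\t200\t.\t+\t.\tgene_id "gA"; exon_id "gA.1";',
        'chr1\tens\texon\t301\t400\t.\t+\t.\tgene_id "gA"; exon_id "gA.2";',
        'chr1\tens\texon\t501\t700\t.\t+\t.\tgene_id "gA"; exon_id "gA.3";',
        'chr1\tens\ttranscript\t100\t700\t.\t+\t.\tgene_id "gA";',
        'chr1\tens\texon\t1001\t1100\t.\t-\t.\tgene_id "gB"; exon_id "gB.1";',
        'chr1\tens\texon\t1201\t1300\t.\t-\t.\tgene_id "gB"; exon_id "gB.2";',
        'chr1\tens\texon\t1401\t1450\t.\t-\t.\tgene_id "gB"; exon_id "gB.3";',
        'chr2\tens\texon\t11\t110\t.\t+\t.\tgene_id "gC"; exon_id "gC.1";',
        'chr2\tens\texon\t211\t310\t.\t+\t.\tgene_id "gC"; exon_id "gC.2";',
        'chr2\tens\texon\t411\t510\t.\t+\t.\tgene_id "gC"; exon_id "gC.3";',
        'chr2\tens\texon\t611\t710\t.\t+\t.\tgene_id "gC"; exon_id "gC.4";',
    ]
    path = tmp_path / "tiny.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
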