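import numpy as np
import pytest

from replikit.msa import AlignedFamily, FamilyRow
from replikit.concat import concatenate_families
from replikit.dca import FrequencyModel


def make_family(name, rows, reference=None):
    """rows: list of (species, seq_id, residues)."""
    return AlignedFamily(
        name=name,
        rows=[FamilyRow(*r) for r in rows],
        reference_seq_id=reference,
    )


@pytest.fixture
def tiny_pair():
    """Two 3-species families with gapless references from species s1."""
    fam_a = make_family(
        "polA",
        [
            ("s1", "s1|a", "ACDEF"),
            ("s2", "s2|a", "ACDEY"),
            ("s3", "s3|a", "AC-EF"),
        ],
        reference="s1|a",
    )
    fam_b = make_family(
        "twinkle",
        [
            ("s1", "s1|b", "GHI"),
            ("s2", "s2|b", "GHW"),
            ("s3", "s3|b", "G-I"),
        ],
        reference="s1|b",
    )
    return fam_a, fam_b


@pytest.fixture
def tiny_paired(tiny_pair):
    fam_a, fam_b = tiny_pair
    return concatenate_families(fam_a, fam_b, linker_length=4)


def freq_from_joint(joint):
    """FrequencyModel for L=2 from an explicit normalized joint table."""
    joint = np.asarray(joint, dtype=float)
    q = joint.shape[0]
    fi = np.stack([joint.sum(axis=1), joint.sum(axis=0)])
    fij = np.empty((2, q, 2, q))
    fij[0, :, 0, :] = np.diag(fi[0])
    fij[1, :, 1, :] = np.diag(fi[1])
    fij[0, :, 1, :] = joint
    fij[1, :, 0, :] = joint.T
    return FrequencyModel(fi=fi, fij=fij, lam=0.0, q=q, meff=1.0)
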