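import numpy as np
import pytest

from furkit.synthetic_data import default_reference_scheme


@pytest.fixture(scope="session")
def scheme():
    """The synthetic PerR-template reference frame shared by all tests."""
    return default_reference_scheme()


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def gotoh_score(a: str, b: str, open_gap: float = 10.0, ext: float = 0.5) -> float:
    """Independent affine-gap global-alignment score oracle (three-state DP).

    A gap of length k costs open + (k-1)*ext; terminal gaps are charged the
    same as internal ones.
    """
    from Bio.Align import substitution_matrices

    B62 = substitution_matrices.load("BLOSUM62")
    NEG = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_gap + (i - 1) * ext)
    for j in range(1, m + 1):
        Y[0][j] = -(open_gap + (j - 1) * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_gap, X[i - 1][j] - ext, Y[i - 1][j] - open_gap)
            Y[i][j] = max(M[i][j - 1] - open_gap, Y[i][j - 1] - ext, X[i][j - 1] - open_gap)
    return float(max(M[n][m], X[n][m], Y[n][m]))
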