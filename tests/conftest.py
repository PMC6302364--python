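import numpy as np
import pytest

from triagekit import CondProbMatrix, ScoreMatrix, sample, three_class_default, two_class_symmetric


@pytest.fixture(scope="session")
def two_class_model():
    return two_class_symmetric()


@pytest.fixture(scope="session")
def three_class_model():
    return three_class_default()


def random_prob_matrix(rng, n, m, labels=None):
    """Row-stochastic matrix with Dirichlet(1,...,1) rows."""
    values = rng.dirichlet(np.ones(m), size=n)
    labels = labels or [f"a_{k + 1}" for k in range(m)]
    return CondProbMatrix(values=values, labels=labels)


def random_score_matrix(rng, n, m, labels=None):
    values = rng.dirichlet(np.ones(m), size=n)
    labels = labels or [f"a_{k + 1}" for k in range(m)]
    return ScoreMatrix(values=values, labels=labels)


def sample_truth_from_rows(rng, probs):
    """Draw one true label per row from that row's conditional distribution."""
    cum = np.cumsum(probs.values, axis=1)
    u = rng.random(probs.n_items)
    idx = (u[:, None] > cum).sum(axis=1)
    return np.asarray(probs.labels, dtype=object)[idx]


def write_score_csv(path, scores, ids=None, truth=None, sep=","):
    """Serialize a score matrix as the delimited table the loader expects."""
    n = scores.n_items
    ids = [f"item{i:03d}" for i in range(n)] if ids is None else list(ids)
    header = ["item_id", *scores.labels] + (["truth"] if truth is not None else [])
    lines = [sep.join(header)]
    for i in range(n):
        cells = [ids[i]] + ["%.17g" % v for v in scores.values[i]]
        if truth is not None:
            cells.append(str(truth[i]))
        lines.append(sep.join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture()
def fifty_row_table(tmp_path, three_class_model):
    """A 50-item synthetic score table with truth, written to disk (seed fixed)."""
    s = sample(three_class_model, 50, seed=502)
    path = write_score_csv(
        tmp_path / "scores50.csv",
        ScoreMatrix(values=s.probs.values, labels=s.probs.labels),
        truth=s.true_labels,
    )
    return path, s
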