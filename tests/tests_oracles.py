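"""Brute-force per-voxel oracles used by the metric tests.

Deliberately written as literal Python loops over voxels, independent
of any array expression used by the implementation.
"""


def loop_metrics(pred, truth, truth_cl, pred_cl, spacing):
    n_cl = det = leak = fp = inter = n_p = n_g = 0
    for z in range(pred.shape[0]):
        for y in range(pred.shape[1]):
            for x in range(pred.shape[2]):
                p, g = bool(pred[z, y, x]), bool(truth[z, y, x])
                n_p += p
                n_g += g
                inter += p and g
                fp += p and not g
                if truth_cl[z, y, x]:
                    n_cl += 1
                    det += p
                if pred_cl[z, y, x] and not g:
                    leak += 1
    return {
        "tl": 100.0 * det / n_cl,
        "cl": 100.0 * leak / n_cl,
        "fpr": 100.0 * fp / n_g,
        "dsc": 2.0 * inter / (n_p + n_g) if (n_p + n_g) else 1.0,
        "length": det * (spacing[0] * spacing[1] * spacing[2]) ** (1.0 / 3.0),
    }
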