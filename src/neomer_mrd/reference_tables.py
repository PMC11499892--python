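"""Published operating points of a 44-patient inoperable localized NSCLC
MRD study, used as fixed numeric inputs.

The study profiled plasma cfDNA at three time points during/after
chemoradiotherapy (TP1: week 4 of treatment, TP2: +1 month, TP3:
+3 months) and reported, per time point, confusion matrices of three
progression predictors against observed progression status: the neomer
risk model, the ctDNA mutation assay, and their OR combination.  These
matrices — together with the TP3 model-vs-assay agreement table — are
the inputs to the metric-replication analysis: all derived statistics
(sensitivity, specificity, PPV, NPV, accuracy, exact binomial CIs,
Cohen's kappa) are recomputed by this package, never copied.

Matrices are (tp, fp, fn, tn) against observed progression.
"""

from neomer_mrd.stats import ConfusionMatrix

CONFUSION_MATRICES: dict[str, dict[str, ConfusionMatrix]] = {
    "TP1": {
        "neomer": ConfusionMatrix(tp=10, fp=1, fn=15, tn=13),
        "mutation": ConfusionMatrix(tp=10, fp=3, fn=15, tn=11),
        "combined": ConfusionMatrix(tp=15, fp=3, fn=10, tn=11),
    },
    "TP2": {
        "neomer": ConfusionMatrix(tp=8, fp=1, fn=12, tn=12),
        "mutation": ConfusionMatrix(tp=9, fp=0, fn=11, tn=13),
        "combined": ConfusionMatrix(tp=11, fp=1, fn=9, tn=12),
    },
    "TP3": {
        "neomer": ConfusionMatrix(tp=5, fp=1, fn=6, tn=13),
        "mutation": ConfusionMatrix(tp=2, fp=2, fn=9, tn=12),
        "combined": ConfusionMatrix(tp=6, fp=2, fn=5, tn=12),
    },
}

# TP3 neomer-model vs mutation-assay agreement among 25 samples:
# 6 model-high, 4 assay-positive, 2 called high by both.
TP3_AGREEMENT = {"a": 2, "b": 4, "c": 2, "d": 17}

# Published point estimates (percent) for the same matrices, kept solely
# so the replication analysis can display recomputed-vs-published side by
# side; every recomputed number comes from stats.metrics.
PUBLISHED_PERCENT: dict[tuple[str, str, str], tuple[float, float, float]] = {
    ("TP1", "neomer", "sensitivity"): (40.0, 21.1, 61.3),
    ("TP1", "neomer", "specificity"): (92.9, 66.1, 99.8),
    ("TP1", "neomer", "ppv"): (90.9, 58.7, 99.8),
    ("TP1", "neomer", "npv"): (46.4, 27.5, 66.1),
    ("TP1", "neomer", "accuracy"): (59.0, 42.1, 74.4),
    ("TP1", "mutation", "sensitivity"): (40.0, 21.1, 61.3),
    ("TP1", "mutation", "specificity"): (78.6, 49.2, 95.3),
    ("TP1", "mutation", "ppv"): (76.9, 46.2, 95.0),
    ("TP1", "mutation", "npv"): (42.3, 23.4, 63.1),
    ("TP1", "mutation", "accuracy"): (53.8, 37.2, 69.9),
    ("TP1", "combined", "sensitivity"): (60.0, 38.7, 78.9),
    ("TP1", "combined", "specificity"): (78.6, 49.2, 95.3),
    ("TP1", "combined", "ppv"): (83.3, 58.6, 96.4),
    ("TP1", "combined", "npv"): (52.4, 29.8, 74.3),
    ("TP1", "combined", "accuracy"): (66.7, 49.8, 80.9),
    ("TP2", "neomer", "sensitivity"): (40.0, 19.1, 63.9),
    ("TP2", "neomer", "specificity"): (92.3, 64.0, 99.8),
    ("TP2", "neomer", "ppv"): (88.9, 51.8, 99.7),
    ("TP2", "neomer", "npv"): (50.0, 29.1, 70.9),
    ("TP2", "neomer", "accuracy"): (60.6, 42.1, 77.1),
    ("TP2", "mutation", "sensitivity"): (45.0, 23.1, 68.5),
    ("TP2", "mutation", "specificity"): (100.0, 75.3, 100.0),
    ("TP2", "mutation", "ppv"): (100.0, 66.4, 100.0),
    ("TP2", "mutation", "npv"): (54.2, 32.8, 74.4),
    ("TP2", "mutation", "accuracy"): (66.7, 48.2, 82.0),
    ("TP2", "combined", "sensitivity"): (55.0, 31.5, 76.9),
    ("TP2", "combined", "specificity"): (92.3, 64.0, 99.8),
    ("TP2", "combined", "ppv"): (91.7, 61.5, 99.8),
    ("TP2", "combined", "npv"): (57.1, 34.0, 78.2),
    ("TP2", "combined", "accuracy"): (69.7, 51.3, 84.4),
    ("TP3", "neomer", "sensitivity"): (45.5, 16.7, 76.6),
    ("TP3", "neomer", "specificity"): (92.9, 66.1, 99.8),
    ("TP3", "neomer", "ppv"): (83.3, 35.9, 99.6),
    ("TP3", "neomer", "npv"): (68.4, 43.4, 87.4),
    ("TP3", "neomer", "accuracy"): (72.0, 50.6, 87.9),
    ("TP3", "mutation", "sensitivity"): (18.2, 2.28, 51.8),
    ("TP3", "mutation", "specificity"): (85.7, 57.2, 98.2),
    ("TP3", "mutation", "ppv"): (50.0, 6.76, 93.2),
    ("TP3", "mutation", "npv"): (57.1, 34.0, 78.2),
    ("TP3", "mutation", "accuracy"): (56.0, 34.9, 75.6),
    ("TP3", "combined", "sensitivity"): (54.5, 23.4, 83.3),
    ("TP3", "combined", "specificity"): (85.7, 57.2, 98.2),
    ("TP3", "combined", "ppv"): (75.0, 34.9, 96.8),
    ("TP3", "combined", "npv"): (70.6, 44.0, 89.7),
    ("TP3", "combined", "accuracy"): (72.0, 50.6, 87.9),
}

TP3_PUBLISHED_KAPPA = 0.2574
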