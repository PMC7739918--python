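{
  "inlet": "ascending aorta",
  "junctions": [
    [["ascending aorta", "distal"], ["aortic arch I", "proximal"], ["brachiocephalic", "proximal"]],
    [["aortic arch I", "distal"], ["L. common carotid", "proximal"], ["aortic arch II", "proximal"]],
    [["aortic arch II", "distal"], ["L. subclavian", "proximal"], ["thoracic aorta", "proximal"]],
    [["brachiocephalic", "distal"], ["R. subclavian", "proximal"], ["R. common carotid", "proximal"]],
    [["R. subclavian", "distal"], ["R. vertebral", "proximal"], ["R. brachial", "proximal"]],
    [["L. subclavian", "distal"], ["L. vertebral", "proximal"], ["L. brachial", "proximal"]],
    [["L. common carotid", "distal"], ["L ext. carotid", "proximal"], ["L int. carotid I", "proximal"]],
    [["R. common carotid", "distal"], ["R ext. carotid", "proximal"], ["R int. carotid I", "proximal"]],
    [["R. vertebral", "distal"], ["R. vertebral II", "proximal"], ["R. PICA", "proximal"]],
    [["L. vertebral", "distal"], ["L. vertebral II", "proximal"], ["L. PICA", "proximal"]],
    [["R. vertebral II", "distal"], ["L. vertebral II", "distal"], ["basilar I", "proximal"]],
    [["basilar I", "distal"], ["basilar II", "proximal"], ["R. AICA", "proximal"], ["L. AICA", "proximal"], ["pontine I", "proximal"], ["pontine II", "proximal"], ["pontine III", "proximal"]],
    [["basilar II", "distal"], ["basilar III", "proximal"], ["pontine IV", "proximal"], ["pontine V", "proximal"], ["pontine VI", "proximal"]],
    [["basilar III", "distal"], ["basilar IV", "proximal"], ["pontine VII", "proximal"], ["pontine VIII", "proximal"], ["pontine IX", "proximal"]],
    [["basilar IV", "distal"], ["basilar V", "proximal"], ["pontine X", "proximal"], ["pontine XI", "proximal"], ["pontine XII", "proximal"]],
    [["basilar V", "distal"], ["R. SCA", "proximal"], ["L. SCA", "proximal"], ["R. PCA, P1", "proximal"], ["L. PCA, P1", "proximal"]],
    [["L int. carotid I", "distal"], ["L. MCA", "proximal"], ["L. ACA, A1", "proximal"], ["L. PCoA", "proximal"]],
    [["R int. carotid I", "distal"], ["R. MCA", "proximal"], ["R. ACA, A1", "proximal"], ["R. PCoA", "proximal"]],
    [["L. ACA, A1", "distal"], ["L. ACA, A2", "proximal"], ["ACoA", "proximal"]],
    [["R. ACA, A1", "distal"], ["R. ACA, A2", "proximal"], ["ACoA", "distal"]],
    [["L. PCA, P1", "distal"], ["L. PCoA", "distal"], ["L. PCA, P2", "proximal"]],
    [["R. PCA, P1", "distal"], ["R. PCoA", "distal"], ["R. PCA, P2", "proximal"]]
  ],
  "labels": {
    "L. MCA": "L MCA",
    "R. MCA": "R MCA",
    "L. ACA, A2": "L ACA",
    "R. ACA, A2": "R ACA",
    "L. PCA, P2": "L PCA",
    "R. PCA, P2": "R PCA",
    "L. ACA, A1": "CoW",
    "R. ACA, A1": "CoW",
    "L. PCA, P1": "CoW",
    "R. PCA, P1": "CoW",
    "ACoA": "CoW",
    "L. PCoA": "CoW",
    "R. PCoA": "CoW",
    "L. SCA": "cerebellum",
    "R. SCA": "cerebellum",
    "L. AICA": "cerebellum",
    "R. AICA": "cerebellum",
    "L. PICA": "cerebellum",
    "R. PICA": "cerebellum",
    "pontine I": "brainstem",
    "pontine II": "brainstem",
    "pontine III": "brainstem",
    "pontine IV": "brainstem",
    "pontine V": "brainstem",
    "pontine VI": "brainstem",
    "pontine VII": "brainstem",
    "pontine VIII": "brainstem",
    "pontine IX": "brainstem",
    "pontine X": "brainstem",
    "pontine XI": "brainstem",
    "pontine XII": "brainstem"
  },
  "outlet_tags": {
    "thoracic aorta": "lower_body",
    "L. brachial": "left_arm",
    "R. brachial": "right_arm"
  },
  "default_outlet_tag": "head",
  "attachment_points": {
    "L MCA": "L. MCA",
    "R MCA": "R. MCA",
    "L ACA": "L. ACA, A2",
    "R ACA": "R. ACA, A2",
    "L PCA": "L. PCA, P2",
    "R PCA": "R. PCA, P2"
  },
  "co_fractions": {
    "lower_body": 0.65,
    "left_arm": 0.05,
    "right_arm": 0.05,
    "head": 0.25
  }
}
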