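"""What does the 'face diet' machinery do?

Clusters surrogate face-embedding vectors into identities with K-means +
the elbow rule, then builds a morph-average face with equal contribution
per identity, demonstrating that the average is insensitive to how often
each identity was seen.
"""

import numpy as np

import droi

# 1. identity clustering: four planted identities, 10 sigma apart
ids, embeddings, labels = droi.generate_identity_embeddings(
    k=4, n_per_identity=60, separation=10.0, seed=3)
clusters, elbow = droi.cluster_identities(ids, embeddings, k_max=8, seed=0)
print(f"planted 4 identities; elbow selected k={elbow.selected_k} "
      f"from the WCSS curve {[round(w) for w in elbow.wcss]}")

# 2. equal-contribution morph average: identity A contributes five dark
#    crops, identity B one bright crop — the average must sit halfway
template = droi.default_face_template()


def constant_crop(value, cid):
    return droi.FaceCrop(crop_id=cid, image=np.full((200, 210), value),
                         landmarks=template.landmarks.copy())


groups = {0: [constant_crop(0.2, f"a{i}") for i in range(5)],
          1: [constant_crop(0.6, "b0")]}
avg = droi.average_faces(groups, template, condition="fixated")
inner = avg.image[80:150, 70:130]  # well inside the face
print(f"average intensity inside the face: {inner.mean():.3f} "
      "(0.4 = equal weight per identity despite 5-vs-1 crop counts)")
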