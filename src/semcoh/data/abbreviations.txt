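# Abbreviation whitelist for sentence segmentation.
# One entry per line; an entry is the exact token (period included) after
# which a sentence boundary is suppressed.  '#' starts a comment.
# Entries are case-sensitive; ambiguous tokens that are also common words
# ("no.", "min.") are deliberately absent.
Dr.
Mr.
Mrs.
Ms.
Mx.
Prof.
Rev.
Hon.
St.
Jr.
Sr.
Capt.
Lt.
Sgt.
Gen.
Col.
e.g.
i.e.
etc.
vs.
cf.
al.
approx.
dept.
Vol.
pp.
Fig.
Eq.
ca.
Mt.
Ave.
Blvd.
Rd.
Inc.
Ltd.
Co.
Corp.
U.S.
U.K.
a.m.
p.m.
Ph.D.
M.D.
B.A.
M.A.
# lowercase courtesy variants seen in informal forum text
dr.
mr.
mrs.
ms.
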