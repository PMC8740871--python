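landmarks:
- name: Tr
  role: fixed
- name: Gl
  role: fixed
- name: N
  role: fixed
- name: Sn
  role: fixed
- name: Ls
  role: fixed
- name: Sto
  role: fixed
- name: Li
  role: fixed
- name: Sl
  role: fixed
- name: Gn
  role: fixed
- name: Zy_l
  role: fixed
- name: Zy_r
  role: fixed
- name: Go_l
  role: fixed
- name: Go_r
  role: fixed
- name: Ch_l
  role: fixed
- name: Ch_r
  role: fixed
- name: Al_l
  role: fixed
- name: Al_r
  role: fixed
- name: Ex_l
  role: fixed
- name: Ex_r
  role: fixed
- name: En_l
  role: fixed
- name: En_r
  role: fixed
- name: Ps_l
  role: fixed
- name: Ps_r
  role: fixed
- name: Pi_l
  role: fixed
- name: Pi_r
  role: fixed
- name: Pu_l
  role: fixed
- name: Pu_r
  role: fixed
- name: EbM_l
  role: fixed
- name: EbM_r
  role: fixed
- name: EbL_l
  role: fixed
- name: EbL_r
  role: fixed
- name: Cph_l
  role: fixed
- name: Cph_r
  role: fixed
- name: Sba_l
  role: fixed
- name: Sba_r
  role: fixed
- name: Ft_l
  role: fixed
- name: Ft_r
  role: fixed
- name: o1_l
  role: semilandmark
- name: o1_r
  role: semilandmark
- name: o2_l
  role: semilandmark
- name: o2_r
  role: semilandmark
- name: o3_l
  role: semilandmark
- name: o3_r
  role: semilandmark
- name: o4_l
  role: semilandmark
- name: o4_r
  role: semilandmark
- name: o5_l
  role: semilandmark
- name: o5_r
  role: semilandmark
- name: o6_l
  role: semilandmark
- name: o6_r
  role: semilandmark
- name: o7_l
  role: semilandmark
- name: o7_r
  role: semilandmark
- name: o8_l
  role: semilandmark
- name: o8_r
  role: semilandmark
- name: o9_l
  role: semilandmark
- name: o9_r
  role: semilandmark
- name: b1_l
  role: semilandmark
- name: b1_r
  role: semilandmark
- name: b2_l
  role: semilandmark
- name: b2_r
  role: semilandmark
- name: b3_l
  role: semilandmark
- name: b3_r
  role: semilandmark
- name: ul1_l
  role: semilandmark
- name: ul1_r
  role: semilandmark
- name: ul2_l
  role: semilandmark
- name: ul2_r
  role: semilandmark
- name: ll1_l
  role: semilandmark
- name: ll1_r
  role: semilandmark
- name: ll2_l
  role: semilandmark
- name: ll2_r
  role: semilandmark
- name: ll3_l
  role: semilandmark
- name: ll3_r
  role: semilandmark
bilateral_pairs:
- - Zy_l
  - Zy_r
- - Go_l
  - Go_r
- - Ch_l
  - Ch_r
- - Al_l
  - Al_r
- - Ex_l
  - Ex_r
- - En_l
  - En_r
- - Ps_l
  - Ps_r
- - Pi_l
  - Pi_r
- - Pu_l
  - Pu_r
- - EbM_l
  - EbM_r
- - EbL_l
  - EbL_r
- - Cph_l
  - Cph_r
- - Sba_l
  - Sba_r
- - Ft_l
  - Ft_r
- - o1_l
  - o1_r
- - o2_l
  - o2_r
- - o3_l
  - o3_r
- - o4_l
  - o4_r
- - o5_l
  - o5_r
- - o6_l
  - o6_r
- - o7_l
  - o7_r
- - o8_l
  - o8_r
- - o9_l
  - o9_r
- - b1_l
  - b1_r
- - b2_l
  - b2_r
- - b3_l
  - b3_r
- - ul1_l
  - ul1_r
- - ul2_l
  - ul2_r
- - ll1_l
  - ll1_r
- - ll2_l
  - ll2_r
- - ll3_l
  - ll3_r
midline:
- Tr
- Gl
- N
- Sn
- Ls
- Sto
- Li
- Sl
- Gn
sliders:
  o1_l:
  - Tr
  - o1_l
  - o2_l
  o1_r:
  - Tr
  - o1_r
  - o2_r
  o2_l:
  - o1_l
  - o2_l
  - o3_l
  o2_r:
  - o1_r
  - o2_r
  - o3_r
  o3_l:
  - o2_l
  - o3_l
  - o4_l
  o3_r:
  - o2_r
  - o3_r
  - o4_r
  o4_l:
  - o3_l
  - o4_l
  - Zy_l
  o4_r:
  - o3_r
  - o4_r
  - Zy_r
  o5_l:
  - Zy_l
  - o5_l
  - o6_l
  o5_r:
  - Zy_r
  - o5_r
  - o6_r
  o6_l:
  - o5_l
  - o6_l
  - Go_l
  o6_r:
  - o5_r
  - o6_r
  - Go_r
  o7_l:
  - Go_l
  - o7_l
  - o8_l
  o7_r:
  - Go_r
  - o7_r
  - o8_r
  o8_l:
  - o7_l
  - o8_l
  - o9_l
  o8_r:
  - o7_r
  - o8_r
  - o9_r
  o9_l:
  - o8_l
  - o9_l
  - Gn
  o9_r:
  - o8_r
  - o9_r
  - Gn
  b1_l:
  - EbM_l
  - b1_l
  - b2_l
  b1_r:
  - EbM_r
  - b1_r
  - b2_r
  b2_l:
  - b1_l
  - b2_l
  - b3_l
  b2_r:
  - b1_r
  - b2_r
  - b3_r
  b3_l:
  - b2_l
  - b3_l
  - EbL_l
  b3_r:
  - b2_r
  - b3_r
  - EbL_r
  ul1_l:
  - Ch_l
  - ul1_l
  - ul2_l
  ul1_r:
  - Ch_r
  - ul1_r
  - ul2_r
  ul2_l:
  - ul1_l
  - ul2_l
  - Cph_l
  ul2_r:
  - ul1_r
  - ul2_r
  - Cph_r
  ll1_l:
  - Ch_l
  - ll1_l
  - ll2_l
  ll1_r:
  - Ch_r
  - ll1_r
  - ll2_r
  ll2_l:
  - ll1_l
  - ll2_l
  - ll3_l
  ll2_r:
  - ll1_r
  - ll2_r
  - ll3_r
  ll3_l:
  - ll2_l
  - ll3_l
  - Li
  ll3_r:
  - ll2_r
  - ll3_r
  - Li
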