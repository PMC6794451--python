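pt_id;braf;vax_protocol;site_baseline;site_post;months_surgery_to_vax;months_vax_to_biopsy;sampling_table1;sampling;bor;os_months;biopsy_response;dth;prior_treatments;following_treatments;cd8_ratio_post_pre;pdl1_pre;pdl1_post
1;V600E;CUP;Lymph node;Lymph node;1;17;on_treatment;on_treatment;CR/8;34;progressing;+;No;CT, High dose IL-2;1,101;7,836;3,022
2;V600E;CUP;Lymph node;Subcutis;15;18;post_treatment;post_treatment;PR/68;87;stable;+;BioCT;Surgery;0,913;0,726;0,402
3;V600E;CUP;Omentum;Stomach;2;24;on_treatment;on_treatment;SD/50;108+;stable;+;BioCT;Surgery, RT;0,823;16,750;6,185
4;WT;Tem;Peritoneum;Subcutis;2;4;on_treatment;on_treatment;SD/4;16;progressing;+;CT, Ipi;RT;0,173;4,744;4,793
5;na;Tem;Subcutis;Omentum;1;4;on_treatment;on_treatment;SD/10;45;progressing;+;RT;Ipi;1,338;11,130;24,700
6;V600E;Tem;Lung;Skin;3;7;on_treatment;post_treatment;SD/9;62;progressing;+;BioCT;low doses IL-2, Ipi;0,521;0,9748;9,203
7;V600E;CUP;Subcutis;Subcutis;10;5;post_treatment;on_treatment;SD/7;22;progressing;+;CT*;Ipi;0,560;0,826;7,519
8;WT;CUP;Jejunum;Adrenal gland;29;4;on_treatment;on_treatment;PR/57;87+;stable;++;CT;Ipi, CT;3,010;0,000;33,639
9;V600E;CUP;Lymph node;Subcutis;3;5;on_treatment;on_treatment;SD/6;23;progressing;+;No;Ipi, vemurafenib, Tem;4,039;0,602;6,530
10;V600E;CUP;Subcutis;Lymph node;12;3;post_treatment;post_treatment;SD/5;18;progressing;+;Biot;RT;0,110;8,771;na
11;WT;CUP;Subcutis;Subcutis;3;9;on_treatment;on_treatment;SD/5;27;progressing;+;No;CT, Ipi;1,051;1,255;13,999
12;WT;CUP;Subcutis;Subcutis;8;4;on_treatment;on_treatment;PD;13;progressing;-;Biot;No;1,355;na;na
13;WT;Vax+INFa;Subcutis;Subcutis;5;3;on_treatment;on_treatment;PD;11;progressing;+;No;Ipi;2,260;1,677;8,201
14;WT;Vax+INFa;Lymph node;Subcutis;0;3;on_treatment;on_treatment;PD;7;progressing;+;No;Ipi;5,013;2,465;11,765
15;WT;Vax only;Subcutis;Brain;4;6;on_treatment;on_treatment;SD/5;8;progressing;+;CT, Ipi;No;1,080;2,379;0,893
16;V600E;CUP;Adrenal gland;Skin;2;5;on_treatment;on_treatment;PD;19;progressing;+;No;Ipi, vemurafenib, BioCT, pembro;5,097;1,709;14,279
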