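release_area,release_region,released,r_7a,r_7g,r_7f,r_7h,r_7e,r_7d,r_4c,r_4b,r_8a,r_8b,r_8c,r_CI,note
IS,7.a,400,1,0,1,1,0,3,0,0,0,0,0,0,
IS,7.f,313,1,1,1,5,0,2,0,0,0,1,0,0,
EC,7.e,2017,0,0,3,0,75,26,6,0,2,1,1,0,recapture digit run ambiguous; grouping chosen to keep most recaptures in the release division
EC,7.d,563,0,0,0,0,8,6,2,0,0,0,0,0,recapture digit run ambiguous; single-digit reading
NS,4.c,205,0,0,0,0,1,3,6,0,0,0,0,0,recapture digit run ambiguous; single-digit reading
NS,4.b,117,1,0,0,0,1,1,3,8,0,0,0,0,recapture digit run ambiguous; single-digit reading
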