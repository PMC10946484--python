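# Independent oracle: classical tau2 estimators and the fixed-weights moment
# estimator / Q-profile interval from metafor, for cross-checking qfmeta.
# Usage: Rscript metafor_oracle.R <csv> <only|always>
suppressMessages(library(metafor))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
to <- ifelse(args[2] == "always", "all", "only0")
dat <- escalc(measure = "OR", ai = d$x_t, bi = d$n_t - d$x_t,
              ci = d$x_c, di = d$n_c - d$x_c, add = 1/2, to = to)
ntilde <- d$n_t * d$n_c / (d$n_t + d$n_c)
ctl <- list(threshold = 1e-10)
out <- list()
for (m in c("DL", "REML", "PM")) {
  out[[m]] <- rma(yi, vi, data = dat, method = m, control = ctl)$tau2
}
out[["GENQ"]] <- rma(yi, vi, data = dat, method = "GENQ", weights = ntilde)$tau2
ciq <- confint(rma(yi, vi, data = dat, method = "PM", control = ctl))
out[["QP_lb"]] <- ciq$random["tau^2", "ci.lb"]
out[["QP_ub"]] <- ciq$random["tau^2", "ci.ub"]
cat(paste(names(out), sapply(out, function(x) sprintf("%.12f", x)),
          sep = "=", collapse = "\n"), "\n")
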